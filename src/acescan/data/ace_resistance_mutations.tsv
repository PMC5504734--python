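# Curated insect acetylcholinesterase (ace1/ace2) target-site resistance mutations.
# Positions use Torpedo californica AChE (PDB 1EA5) numbering, the field convention
# for naming AChE mutations (e.g. G119S). native_position is left blank where the
# original report gives only the Torpedo-numbered name; the pipeline recovers the
# native codon by global alignment to the Torpedo chain.
species	gene	wild_type_aa	native_position	torpedo_position	mutant_aa	wild_type_codon	mutant_codon	source
Drosophila melanogaster	ace2	F		115	S			Mutero et al. 1994 PNAS
Drosophila melanogaster	ace2	I		199	V			Mutero et al. 1994 PNAS
Drosophila melanogaster	ace2	G		303	A			Mutero et al. 1994 PNAS
Drosophila melanogaster	ace2	F		368	Y			Mutero et al. 1994 PNAS
Musca domestica	ace2	V		180	L			Walsh et al. 2001 Biochem J
Musca domestica	ace2	G		262	A			Walsh et al. 2001 Biochem J
Musca domestica	ace2	G		262	V			Walsh et al. 2001 Biochem J
Musca domestica	ace2	F		327	Y			Walsh et al. 2001 Biochem J
Musca domestica	ace2	G		365	A			Walsh et al. 2001 Biochem J
Anopheles gambiae	ace1	G		119	S			Weill et al. 2004 Insect Mol Biol
Plutella xylostella	ace1	A		201	S			Lee et al. 2007 Insect Biochem Mol Biol
Plutella xylostella	ace1	G		227	A			Lee et al. 2007 Insect Biochem Mol Biol
Nasonia vitripennis	ace2	G		118	S			RNA-Seq mutation survey
Chilo suppressalis	ace1	F		290	V			Xu et al. 2015 (triazophos resistance)
Chilo suppressalis	ace1	F		330	S			Xu et al. 2015 (triazophos resistance)
Chilo suppressalis	ace1	F		331	H			Xu et al. 2015 (triazophos resistance)
Chilo suppressalis	ace1	S		332	L			Xu et al. 2015 (triazophos resistance)
Bemisia tabaci	ace1	S		331	W			RNA-Seq mutation survey
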