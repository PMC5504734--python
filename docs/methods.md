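# Methods

## Model and procedure

The package estimates per-site resistance-allele frequencies from short
reads by exact fragment matching rather than alignment-based variant
calling. For a catalogued substitution at codon *c* of a coding sequence,
the susceptible fragment is the CDS substring spanning codon *c* plus
symmetric flanks, and each resistant fragment is the same window with the
codon replaced by a codon of the mutant amino acid. A read is classified
at a site if it contains one of the site's fragments as an exact substring
on either strand. The estimator

    f̂ = R / (R + S)

(R resistant reads, S susceptible reads) is the binomial MLE of the
resistant proportion among site-covering reads, under the assumptions
that (i) both alleles are sequenced with equal efficiency, (ii) an exact
11-mer match identifies the allele uniquely within the transcriptome, and
(iii) errors inside the window knock a read out of *both* allele classes
symmetrically. Assumption (iii) is why moderate error rates leave the
estimator approximately unbiased: a fragment of length L survives
error-free with probability (1−e)^L regardless of allele, thinning both
counts by the same factor (at e = 0.005, L = 11 about 5.4% of covering
reads are lost).

Because expression, not genome copy number, drives read counts, f̂ is a
*transcript* allele frequency; allele-specific expression can shift it away
from the genomic allele frequency. Very low f̂ should be read cautiously —
at the survival analysis above, a single miscalled fragment can register as
a resistant read.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| fragment_length | 11 nt | codon + 4-nt flanks; 9–13 allowed ((L−3) must be even). Longer windows lose reads whose site is near a read end; shorter ones lose transcriptome-level uniqueness. |
| k (pre-filter) | 15 | k-mer size of the ace-membership shortlist; 4^15 ≫ transcriptome size, so random hits are rare. |
| min_shared_kmers | 2 | a read must share ≥ 2 k-mers with the reference CDS set (either strand); 2 suppresses single-k-mer chance hits. |
| Q30 threshold | 0.85 | dataset-level cleanliness criterion (fraction of bases with Phred ≥ 30); warn-and-continue by default, `--strict-qc` aborts. |
| min CDS length | 1800 bp | curation filter for candidate ace sequences (applied to the nucleotide CDS; disable with 0 for toy data). |
| alignment scoring | BLOSUM62, gap open 10 / extend 1 | standard protein-numbering transfer; fully configurable, including simple match/mismatch scoring. |

## Position numbering

Mutations are named in *Torpedo californica* AChE numbering: the native
residue index is mapped through a global alignment of the species protein
to the supplied Torpedo chain (1EA5). Torpedo positions are 1-based
indices into the supplied FASTA; any mature-protein offset convention must
be encoded in that FASTA itself. Catalogue records may store the native
position explicitly (it then takes precedence) or leave it blank, in which
case the pipeline inverts the position map. Ties among co-optimal
alignments are broken deterministically by the aligner's fixed traceback
order; only the alignment score is contract-level, and it is verified
against exhaustive enumeration in the tests.

## Ambiguity, edge cases, numerical choices

- **Ambiguous reads** (both alleles of one site in one read — possible only
  through sequencing error or chimerism) are counted separately and
  excluded from the denominator: conservative and auditable.
- **Zero coverage** reports frequency `NA`, never 0: absence of evidence is
  not evidence of susceptibility.
- **N bases** are scanned as-is and can never match a fragment.
- **Duplicate read IDs** are allowed; counting is per record.
- **Multiple sites per read**: each site is counted independently, so one
  read may contribute to several sites.
- **Fragment collisions**: building the index fails loudly if one k-mer
  (or its reverse complement) is claimed by two different (site, allele)
  entries — silent misattribution is never possible.
- Mutant codons are enumerated over the full standard-code synonym set by
  default; a profile may pin the published codon, which restores
  specificity when the synonym set would be too permissive. Enumeration is
  a superset of any single-codon convention, so it can only add resistant
  sensitivity, never lose it.
- Reverse-strand SAM records are reverse-complemented back to read
  orientation on ingestion; unmapped, secondary and supplementary records
  are ignored.

## Simulator

The simulator emulates the data regime the scanner targets: single-end
reads of constant length and quality drawn uniformly from the CDS on a
random strand, per-read per-site haplotype draws at the requested
resistant-allele frequency, i.i.d. substitution errors (no indels —
Illumina's dominant error mode, and the scanner is exact-match), and
optional background reads from a dinucleotide-preserving
(Altschul–Erickson) shuffle of the CDS, rejected until the shuffle shares
no fragment-length k-mer with the site catalogue. Every read carries a
truth label (origin, per-site haplotype, whether the read fully covers each
fragment window), so error-free runs can be checked for *exact* recovery:
the pipeline estimate must equal the realised resistant fraction among
covering reads.

What the simulator does **not** model — expression structure, paired ends,
position-dependent quality, linkage between sites on one transcript, a
real off-target transcriptome — bounds what passing tests show: they
validate the counting machinery and its invariances, not performance on
any particular real dataset. The shuffled-CDS background exercises the
pre-filter's specificity claim without external data, but a real
transcriptome contains paralogues (other carboxylesterases) whose
similarity to ace is biological, not compositional.

Default problem sizes (2,000 reads per run, 20 seeds for the stochastic
check, 500 enumeration pairs, 10,000 scanner-oracle reads) were chosen as
the smallest sizes at which the binomial checks are well-powered.

## Bundled mutation catalogue

The shipped TSV contains the 18 mutations reported by name in the
functional literature on the seven focal pest species (e.g. the four
*D. melanogaster* and five *M. domestica* ace2 mutations, *A. gambiae*
G119S, *P. xylostella* A201S/G227A, the *C. suppressalis* ace1 set). It is
a minimum catalogue, not an exhaustive survey of published reports; species
attribution of a few RNA-Seq-era records is the package's own reading of
the source tables. Users monitoring other species should extend the TSV —
validation (codon/amino-acid consistency, duplicate detection, wild-type
residue cross-checks against a reference) runs on every load.

## Known limitations

- Exact matching cannot see a site whose fragment window contains a
  sequencing error or a linked polymorphism; an aligner-based shortlist
  with mismatch tolerance feeds the same scanner via SAM ingestion, but
  the scan itself stays exact.
- Substitutions only: indel alleles are out of scope.
- Frequencies from different samples are comparable only as proportions;
  no cross-sample statistics are computed (export via `summarize` and use a
  statistics package).
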