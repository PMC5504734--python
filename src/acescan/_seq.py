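"""Small nucleotide/codon helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code; '*' for stop."""
    codon = codon.upper()
    if codon in _STANDARD.stop_codons:
        return "*"
    try:
        return _STANDARD.forward_table[codon]
    except KeyError:
        raise ValueError(f"not a valid unambiguous codon: {codon!r}") from None


def codons_for(amino_acid: str) -> list[str]:
    """All standard-code codons encoding `amino_acid`, lexicographically sorted."""
    aa = amino_acid.upper()
    out = sorted(c for c, a in _STANDARD.forward_table.items() if a == aa)
    if not out:
        raise ValueError(f"no codon encodes amino acid {amino_acid!r}")
    return out


def translate_cds(cds: str) -> str:
    """Translate a CDS, requiring length % 3 == 0 and no internal stop.

    A single trailing stop codon is allowed and removed.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        aa = translate_codon(cds[3 * i : 3 * i + 3])
        if aa == "*":
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon at codon {i + 1}")
            break
        aas.append(aa)
    return "".join(aas)
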