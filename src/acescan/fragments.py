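"""Build the per-site susceptible/resistant fragment catalogue.

For each profiled mutation the coding sequence yields one susceptible
fragment — the 11-nt window centred on the wild-type codon (4 nt flank +
codon + 4 nt flank) — and one resistant fragment per mutant codon (all
synonymous codons of the mutant amino acid, unless the profile pins an
observed codon).  Reads are later classified by exact containment of these
fragments on either strand, so the index refuses any 11-mer claimed by two
different (site, allele) entries.

The 11-nt default reflects the short-read trade-off: longer fragments lose
reads whose mutation sits near a read end, shorter ones start matching
non-ace transcripts.  Lengths 9-13 (odd flank arithmetic: length - 3 must be
even) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._seq import codons_for, reverse_complement, translate_codon
from .profile import MutationRecord
from .reference import AceReference

SUSCEPTIBLE = "susceptible"
RESISTANT = "resistant"

DEFAULT_FRAGMENT_LENGTH = 11


class FragmentError(ValueError):
    pass


class FragmentCollisionError(FragmentError):
    """The same k-mer is claimed by two different (site, allele) entries."""


@dataclass(frozen=True)
class FragmentSet:
    """Susceptible and resistant fragments covering one mutation site."""

    site_id: str
    mutation_name: str
    species: str
    gene: str
    cds_codon_index: int  # 1-based codon number in the CDS
    cds_window: tuple[int, int]  # 1-based inclusive nucleotide coordinates
    susceptible_fragment: str
    resistant_fragments: tuple[str, ...]
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH


def build_site_fragments(
    reference: AceReference,
    record: MutationRecord,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    *,
    native_position: int | None = None,
) -> FragmentSet:
    """Cut the codon-centred window from the CDS and substitute mutant codons.

    `native_position` overrides (or supplies, when the profile stores only the
    Torpedo-numbered name) the record's native residue index.
    """
    if fragment_length < 5 or (fragment_length - 3) % 2 != 0:
        raise FragmentError(
            f"fragment_length must be >= 5 with (length - 3) even, got {fragment_length}"
        )
    position = native_position or record.native_position
    if position is None:
        raise FragmentError(
            f"{record.name}: no native position; supply one or attach a PositionMap"
        )
    n_codons = len(reference.cds) // 3
    if not 1 <= position <= n_codons:
        raise FragmentError(
            f"{record.name}: codon {position} outside CDS of {n_codons} codons"
        )
    flank = (fragment_length - 3) // 2
    codon_start = 3 * (position - 1)  # 0-based
    window_start = codon_start - flank
    window_end = codon_start + 3 + flank  # 0-based exclusive
    if window_start < 0 or window_end > len(reference.cds):
        raise FragmentError(
            f"{record.name}: insufficient flank for a {fragment_length}-nt window "
            f"around codon {position}"
        )
    wild_codon = reference.cds[codon_start : codon_start + 3]
    wild_aa = translate_codon(wild_codon)
    if wild_aa != record.wild_type_aa:
        raise FragmentError(
            f"{record.name}: CDS codon {position} ({wild_codon}) encodes {wild_aa}, "
            f"profile says wild type {record.wild_type_aa}"
        )
    if record.wild_type_codon and record.wild_type_codon != wild_codon:
        raise FragmentError(
            f"{record.name}: CDS codon {position} is {wild_codon}, profile pins "
            f"wild-type codon {record.wild_type_codon}"
        )
    susceptible = reference.cds[window_start:window_end]
    mutant_codons = (
        [record.mutant_codon] if record.mutant_codon else codons_for(record.mutant_aa)
    )
    left = susceptible[:flank]
    right = susceptible[flank + 3 :]
    resistant = tuple(left + codon + right for codon in mutant_codons)
    assert all(len(f) == fragment_length for f in resistant)
    assert susceptible not in resistant  # aa differ, so codons differ
    return FragmentSet(
        site_id=f"{reference.species}:{reference.gene}:{record.torpedo_position}:{record.mutant_aa}",
        mutation_name=record.name,
        species=reference.species,
        gene=reference.gene,
        cds_codon_index=position,
        cds_window=(window_start + 1, window_end),
        susceptible_fragment=susceptible,
        resistant_fragments=resistant,
        fragment_length=fragment_length,
    )


@dataclass
class FragmentIndex:
    """Exact-match lookup: k-mer (either strand) -> (site_id, allele)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    fragment_sets: list[FragmentSet] = field(default_factory=list)

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        return tuple(sorted({len(k) for k in self.entries}))

    @property
    def site_ids(self) -> list[str]:
        return [fs.site_id for fs in self.fragment_sets]

    def lookup(self, kmer: str) -> tuple[str, str] | None:
        return self.entries.get(kmer)

    def _add(self, fragment: str, site_id: str, allele: str) -> None:
        for key in (fragment, reverse_complement(fragment)):
            existing = self.entries.get(key)
            if existing is not None and existing != (site_id, allele):
                raise FragmentCollisionError(
                    f"fragment {key} claimed by {existing} and ({site_id!r}, {allele!r})"
                )
            self.entries[key] = (site_id, allele)


def build_fragment_index(fragment_sets: Iterable[FragmentSet]) -> FragmentIndex:
    """Index every fragment and its reverse complement; collisions abort."""
    fragment_sets = list(fragment_sets)
    if not fragment_sets:
        raise FragmentError("no fragment sets to index")
    index = FragmentIndex(fragment_sets=fragment_sets)
    for fs in fragment_sets:
        index._add(fs.susceptible_fragment, fs.site_id, SUSCEPTIBLE)
        for frag in fs.resistant_fragments:
            index._add(frag, fs.site_id, RESISTANT)
    return index


def write_fragments_tsv(fragment_sets: Iterable[FragmentSet], path: str | Path) -> None:
    """Audit export: one row per fragment with its CDS window."""
    with open(path, "w") as fh:
        fh.write("site_id\tmutation_name\tallele\tfragment\tcds_start\tcds_end\n")
        for fs in fragment_sets:
            start, end = fs.cds_window
            fh.write(
                f"{fs.site_id}\t{fs.mutation_name}\t{SUSCEPTIBLE}"
                f"\t{fs.susceptible_fragment}\t{start}\t{end}\n"
            )
            for frag in fs.resistant_fragments:
                fh.write(
                    f"{fs.site_id}\t{fs.mutation_name}\t{RESISTANT}\t{frag}\t{start}\t{end}\n"
                )
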