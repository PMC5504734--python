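"""ace reference sequences and Torpedo-numbering position maps.

Insect AChE mutations are conventionally named by the residue number of the
aligned position in *Torpedo californica* AChE (PDB 1EA5), e.g. G119S.  This
module loads and validates ace1/ace2 coding sequences, and builds the
native-residue -> Torpedo-residue map through a global protein alignment.

Validation follows the conventions used when curating insect AChE sets:
coding sequences shorter than 1800 bp are rejected, and the translated
protein must carry the two conserved motifs WIY(F)GGG and FGESAE.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import DNA_ALPHABET, translate_cds

MOTIF_1 = re.compile(r"WI[YF]GGG")
MOTIF_2 = re.compile(r"FGESAE")

GENES = ("ace1", "ace2")


class ReferenceError(ValueError):
    """A reference sequence failed validation."""


@dataclass(frozen=True)
class AceReference:
    """A validated ace coding sequence and its translation."""

    species: str
    gene: str
    accession: str
    cds: str
    protein: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ReferenceError(f"gene must be one of {GENES}, got {self.gene!r}")


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise protein alignment (gapped rows plus score)."""

    aligned_query: str
    aligned_target: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("gapped rows differ in length")


@dataclass(frozen=True)
class MotifReport:
    motif1_position: int | None  # 1-based start of WIY(F)GGG, None if absent
    motif2_position: int | None  # 1-based start of FGESAE
    both_found: bool


@dataclass
class PositionMap:
    """Native residue index -> Torpedo residue index (None opposite a gap)."""

    query_species: str
    query_gene: str
    pairs: list[tuple[int, int | None]] = field(default_factory=list)

    def torpedo(self, native_position: int) -> int | None:
        if not 1 <= native_position <= len(self.pairs):
            raise IndexError(
                f"native position {native_position} outside 1..{len(self.pairs)}"
            )
        native, torpedo = self.pairs[native_position - 1]
        assert native == native_position
        return torpedo

    def native(self, torpedo_position: int) -> int | None:
        """Inverse lookup: the native residue aligned to a Torpedo residue."""
        for nat, tor in self.pairs:
            if tor == torpedo_position:
                return nat
        return None

    def to_tsv(self, path: str | Path, query_protein: str, target_protein: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "species\tgene\tnative_position\tnative_residue"
                "\ttorpedo_position\ttorpedo_residue\n"
            )
            for nat, tor in self.pairs:
                tor_res = target_protein[tor - 1] if tor is not None else ""
                fh.write(
                    f"{self.query_species}\t{self.query_gene}\t{nat}"
                    f"\t{query_protein[nat - 1]}\t{'' if tor is None else tor}"
                    f"\t{tor_res}\n"
                )


def check_motifs(protein: str) -> MotifReport:
    """Locate the two conserved AChE motifs, WIY(F)GGG and FGESAE.

    Returns 1-based start positions (or None); absence is reported, not raised.
    """
    if not protein:
        raise ValueError("empty protein")
    m1 = MOTIF_1.search(protein)
    m2 = MOTIF_2.search(protein)
    return MotifReport(
        motif1_position=m1.start() + 1 if m1 else None,
        motif2_position=m2.start() + 1 if m2 else None,
        both_found=bool(m1 and m2),
    )


def load_reference(
    fasta_path: str | Path,
    gene: str,
    species: str,
    *,
    record_id: str | None = None,
    min_cds_length: int = 1800,
    require_motifs: bool = True,
) -> AceReference:
    """Load one ace CDS from a (possibly multi-record) FASTA and validate it.

    The CDS must be unambiguous A/C/G/T, divisible by 3, free of internal
    stops, and at least `min_cds_length` nucleotides (0 disables the filter).
    With `require_motifs`, the translation must contain both conserved motifs.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    if record_id is None:
        if len(records) > 1:
            raise ReferenceError(
                f"{fasta_path} has {len(records)} records; pass record_id"
            )
        record = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record_id not in by_id:
            raise ReferenceError(f"record {record_id!r} not found in {fasta_path}")
        record = by_id[record_id]

    cds = str(record.seq).upper()
    bad = set(cds) - DNA_ALPHABET
    if bad:
        raise ReferenceError(
            f"CDS contains ambiguous or non-DNA characters: {sorted(bad)}"
        )
    if min_cds_length and len(cds) < min_cds_length:
        raise ReferenceError(
            f"CDS length {len(cds)} is below the {min_cds_length} bp filter"
        )
    try:
        protein = translate_cds(cds)
    except ValueError as exc:
        raise ReferenceError(str(exc)) from exc
    if require_motifs:
        report = check_motifs(protein)
        if not report.both_found:
            missing = []
            if report.motif1_position is None:
                missing.append("WIY(F)GGG")
            if report.motif2_position is None:
                missing.append("FGESAE")
            raise ReferenceError(f"conserved motif(s) missing: {', '.join(missing)}")
    return AceReference(
        species=species, gene=gene, accession=record.id, cds=cds, protein=protein
    )


def load_protein(fasta_path: str | Path, record_id: str | None = None) -> str:
    """Load one protein sequence (e.g. the Torpedo 1EA5 chain) from FASTA."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    if record_id is not None:
        records = [r for r in records if r.id == record_id]
        if not records:
            raise ReferenceError(f"record {record_id!r} not found in {fasta_path}")
    return str(records[0].seq).upper()


def _make_aligner(
    matrix: str | None,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # positive penalties; a run of length L scores -(gap_open + (L-1)*gap_extend)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    query: str,
    target: str,
    *,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Needleman-Wunsch global protein alignment with affine gaps.

    Defaults (BLOSUM62, open 10 / extend 1) suit residue-numbering transfer
    between AChE orthologs.  Pass ``matrix=None`` for simple match/mismatch
    scoring.  Ties among co-optimal paths are broken deterministically.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(query, target)[0]
    return AlignmentResult(
        aligned_query=alignment[0],
        aligned_target=alignment[1],
        score=float(alignment.score),
    )


def build_position_map(
    alignment: AlignmentResult, species: str = "", gene: str = ""
) -> PositionMap:
    """Walk the gapped rows in lockstep, pairing each query residue with the
    target residue it aligns to (None opposite a target gap)."""
    pairs: list[tuple[int, int | None]] = []
    native = torpedo = 0
    for q, t in zip(alignment.aligned_query, alignment.aligned_target):
        if t != "-":
            torpedo += 1
        if q != "-":
            native += 1
            pairs.append((native, torpedo if t != "-" else None))
    return PositionMap(query_species=species, query_gene=gene, pairs=pairs)


def torpedo_position(position_map: PositionMap, native_position: int) -> int | None:
    """Torpedo residue aligned to `native_position`, or None at a gap."""
    return position_map.torpedo(native_position)
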