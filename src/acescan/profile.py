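"""Curated catalogue of known ace resistance mutations, with TSV I/O.

Each record is one published target-site substitution, named in Torpedo
numbering (the field convention: G119S means glycine at aligned Torpedo
position 119 replaced by serine).  The bundled profile covers the mutations
reported in functional studies of *D. melanogaster*, *M. domestica*,
*A. gambiae*, *P. xylostella*, *N. vitripennis*, *C. suppressalis* and
*B. tabaci*; users extend it by editing the TSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

from ._seq import translate_codon
from .reference import AceReference, GENES, PositionMap

BUNDLED_PROFILE = "ace_resistance_mutations.tsv"

_COLUMNS = [
    "species",
    "gene",
    "wild_type_aa",
    "native_position",
    "torpedo_position",
    "mutant_aa",
    "wild_type_codon",
    "mutant_codon",
    "source",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ProfileError(ValueError):
    """The mutation profile TSV failed validation."""


@dataclass(frozen=True)
class MutationRecord:
    """One known resistance mutation of ace1 or ace2."""

    species: str
    gene: str
    wild_type_aa: str
    mutant_aa: str
    torpedo_position: int
    native_position: int | None = None  # unknown for Torpedo-numbered reports
    wild_type_codon: str | None = None
    mutant_codon: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ProfileError("; ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        if self.gene not in GENES:
            problems.append(f"unknown gene label {self.gene!r}")
        if self.wild_type_aa not in _AA:
            problems.append(f"invalid wild-type amino acid {self.wild_type_aa!r}")
        if self.mutant_aa not in _AA:
            problems.append(f"invalid mutant amino acid {self.mutant_aa!r}")
        if self.wild_type_aa == self.mutant_aa:
            problems.append("wild-type and mutant amino acids are identical")
        if self.torpedo_position < 1:
            problems.append("torpedo_position must be >= 1")
        if self.native_position is not None and self.native_position < 1:
            problems.append("native_position must be >= 1")
        for label, codon, aa in (
            ("wild_type_codon", self.wild_type_codon, self.wild_type_aa),
            ("mutant_codon", self.mutant_codon, self.mutant_aa),
        ):
            if codon is None:
                continue
            try:
                got = translate_codon(codon)
            except ValueError:
                problems.append(f"{label} {codon!r} is not a valid codon")
                continue
            if got != aa:
                problems.append(f"{label} {codon} encodes {got}, expected {aa}")
        return problems

    @property
    def name(self) -> str:
        """Field-convention name, e.g. G119S (Torpedo numbering)."""
        return f"{self.wild_type_aa}{self.torpedo_position}{self.mutant_aa}"

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.species, self.gene, self.torpedo_position, self.mutant_aa)


@dataclass
class MutationProfile:
    records: list[MutationRecord]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: dict[tuple, int] = {}
        for i, rec in enumerate(self.records):
            if rec.key in seen:
                raise ProfileError(
                    f"duplicate record {rec.name} ({rec.species}, {rec.gene}): "
                    f"rows {seen[rec.key] + 1} and {i + 1}"
                )
            seen[rec.key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, species: str | None = None, gene: str | None = None) -> "MutationProfile":
        recs = [
            r
            for r in self.records
            if (species is None or r.species == species)
            and (gene is None or r.gene == gene)
        ]
        return MutationProfile(records=recs, version=self.version)

    def names(self) -> set[str]:
        return {r.name for r in self.records}


@dataclass(frozen=True)
class ValidationReport:
    record: MutationRecord
    passed: bool
    messages: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _parse_row(line_no: int, fields: dict[str, str]) -> MutationRecord:
    def opt(key: str) -> str | None:
        v = fields.get(key, "").strip()
        return v or None

    native = opt("native_position")
    try:
        return MutationRecord(
            species=fields["species"].strip(),
            gene=fields["gene"].strip(),
            wild_type_aa=fields["wild_type_aa"].strip().upper(),
            mutant_aa=fields["mutant_aa"].strip().upper(),
            torpedo_position=int(fields["torpedo_position"]),
            native_position=int(native) if native else None,
            wild_type_codon=(opt("wild_type_codon") or "").upper() or None,
            mutant_codon=(opt("mutant_codon") or "").upper() or None,
            source=fields.get("source", "").strip(),
        )
    except (KeyError, ValueError) as exc:
        raise ProfileError(f"line {line_no}: {exc}") from exc


def load_profile(tsv_path: str | Path, version: str | None = None) -> MutationProfile:
    """Load and validate a mutation-profile TSV ('#' comments allowed).

    Malformed rows are reported with their line numbers; any failure raises
    :class:`ProfileError` listing every problem found.
    """
    tsv_path = Path(tsv_path)
    header: list[str] | None = None
    records: list[MutationRecord] = []
    problems: list[str] = []
    with open(tsv_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [h.strip() for h in parts]
                missing = [c for c in _COLUMNS[:6] if c not in header]
                if missing:
                    raise ProfileError(f"header missing columns: {missing}")
                continue
            fields = dict(zip(header, parts))
            try:
                records.append(_parse_row(line_no, fields))
            except ProfileError as exc:
                problems.append(str(exc))
    if header is None:
        raise ProfileError(f"{tsv_path}: no header line")
    if problems:
        raise ProfileError(f"{tsv_path}: " + " | ".join(problems))
    return MutationProfile(records=records, version=version or tsv_path.stem)


def write_profile(profile: MutationProfile, tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in profile:
            fh.write(
                "\t".join(
                    [
                        r.species,
                        r.gene,
                        r.wild_type_aa,
                        "" if r.native_position is None else str(r.native_position),
                        str(r.torpedo_position),
                        r.mutant_aa,
                        r.wild_type_codon or "",
                        r.mutant_codon or "",
                        r.source,
                    ]
                )
                + "\n"
            )


def bundled_profile() -> MutationProfile:
    """The profile shipped with the package (text-reported mutations)."""
    path = importlib.resources.files("acescan.data") / BUNDLED_PROFILE
    return load_profile(str(path), version="builtin-1")


def count_profile(profile: MutationProfile, gene: str) -> tuple[int, int]:
    """(number of mutations, number of distinct Torpedo positions) for a gene."""
    if gene not in GENES:
        raise ValueError(f"gene must be one of {GENES}")
    recs = [r for r in profile if r.gene == gene]
    return len(recs), len({r.torpedo_position for r in recs})


def validate_against_reference(
    record: MutationRecord,
    reference: AceReference,
    position_map: PositionMap | None = None,
) -> ValidationReport:
    """Check a record against a species reference protein.

    Confirms the wild-type residue at native_position; with a PositionMap,
    cross-checks the stated Torpedo position.  A Torpedo disagreement is a
    warning (numbering conventions vary); a residue mismatch is a failure.
    """
    messages: list[str] = []
    warnings: list[str] = []
    native = record.native_position
    if native is None and position_map is not None:
        native = position_map.native(record.torpedo_position)
        if native is None:
            messages.append(
                f"Torpedo position {record.torpedo_position} aligns to a gap "
                f"in {reference.species} {reference.gene}"
            )
    if native is not None:
        if native > len(reference.protein):
            messages.append(
                f"native position {native} beyond protein length "
                f"{len(reference.protein)}"
            )
        else:
            residue = reference.protein[native - 1]
            if residue != record.wild_type_aa:
                messages.append(
                    f"reference residue at native position {native} is {residue}, "
                    f"record says wild type {record.wild_type_aa}"
                )
        if position_map is not None and record.native_position is not None:
            mapped = position_map.torpedo(record.native_position)
            if mapped != record.torpedo_position:
                warnings.append(
                    f"PositionMap puts native {record.native_position} at Torpedo "
                    f"{mapped}, record says {record.torpedo_position}"
                )
    elif position_map is None:
        warnings.append("no native position and no PositionMap; residue not checked")
    return ValidationReport(
        record=record, passed=not messages, messages=messages, warnings=warnings
    )


def resolve_native_position(
    record: MutationRecord, position_map: PositionMap
) -> int:
    """Native residue index for a record, via its Torpedo position if needed."""
    if record.native_position is not None:
        return record.native_position
    native = position_map.native(record.torpedo_position)
    if native is None:
        raise ProfileError(
            f"{record.name}: Torpedo position {record.torpedo_position} has no "
            f"aligned residue in {position_map.query_species} {position_map.query_gene}"
        )
    return native


def attach_native_positions(
    profile: MutationProfile, position_map: PositionMap
) -> MutationProfile:
    """Return a copy of the profile with native positions filled in."""
    recs = []
    for r in profile:
        if r.native_position is None:
            recs.append(replace(r, native_position=resolve_native_position(r, position_map)))
        else:
            recs.append(r)
    return MutationProfile(records=recs, version=profile.version)
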