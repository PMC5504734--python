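"""Synthetic RNA-Seq reads from an ace CDS with known ground truth.

Reads are drawn uniformly along the coding sequence, on a random strand,
from a haplotype chosen per site with the requested resistant-allele
frequency; sequencing errors are i.i.d. substitutions.  Off-target
background reads come from a dinucleotide-preserving shuffle of the CDS
that is rejected until it shares no fragment-length k-mer with the site
catalogue, so background can never produce a fragment hit.  Every read is
emitted with a truth label (origin, per-site haplotype, whether it fully
covers each site's fragment window), which makes the whole pipeline
testable without any external dataset.

Simplifications relative to real RNA-Seq: uniform coverage (no expression
structure), single-end reads, constant base quality, substitution-only
errors, and per-site-independent haplotype draws (no linkage between
sites on one transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import codons_for, reverse_complement
from .classify import ReadRecord
from .fragments import FragmentIndex, FragmentSet, build_fragment_index, build_site_fragments
from .profile import MutationRecord
from .reference import AceReference

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSite:
    """One simulated mutation site: which record, at what allele frequency."""

    record: MutationRecord
    resistant_frequency: float
    mutant_codon: str | None = None  # pin one codon; default draws per read
    native_position: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.resistant_frequency <= 1.0:
            raise ValueError("resistant_frequency must be in [0, 1]")


@dataclass
class SimulationSpec:
    reference: AceReference
    sites: list[SimSite]
    n_reads: int = 2000
    read_length: int = 100
    error_rate: float = 0.0
    background_fraction: float = 0.0
    seed: int = 0
    base_quality: int = 40
    fragment_length: int = 11

    def __post_init__(self) -> None:
        if self.read_length > len(self.reference.cds):
            raise ValueError("read_length exceeds CDS length")
        if self.read_length < self.fragment_length:
            raise ValueError("read_length shorter than fragment_length")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")


@dataclass
class SimulationResult:
    reads: list[ReadRecord]
    truth: pd.DataFrame
    fragment_sets: list[FragmentSet] = field(default_factory=list)


def _doublet_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: random sequence with the same dinucleotide
    counts (an Eulerian-path resampling of the doublet graph)."""
    if len(seq) < 3:
        return seq
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    for _ in range(1000):
        # pick a tentative final out-edge for every non-terminal vertex
        finals: dict[str, str] = {}
        for v in vertices:
            if v != last and edges[v]:
                finals[v] = edges[v][rng.integers(len(edges[v]))]
        # the final edges must lead every vertex to the terminal one
        ok = True
        for v in finals:
            seen = set()
            u: str | None = v
            while u != last and u is not None and u not in seen:
                seen.add(u)
                u = finals.get(u)
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - effectively unreachable for DNA
        raise RuntimeError("doublet shuffle failed to find an Eulerian ordering")
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in finals:
            rest.remove(finals[v])
        rng.shuffle(rest)
        if v in finals:
            rest.append(finals[v])
        ordered[v] = rest
    out = [seq[0]]
    cursor = {v: 0 for v in vertices}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[u][cursor[u]]
        cursor[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def shuffle_background(
    cds: str,
    seed: int | np.random.Generator,
    forbidden: FragmentIndex | None = None,
    max_tries: int = 100,
) -> str:
    """Background sequence: same length and dinucleotide composition as the
    CDS, sharing no indexed fragment k-mer (rejection sampling)."""
    if not cds:
        raise ValueError("empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        shuffled = _doublet_shuffle(cds, rng)
        if forbidden is None or not _contains_any(shuffled, forbidden):
            return shuffled
    raise RuntimeError(f"no fragment-free shuffle found in {max_tries} tries")


def _contains_any(seq: str, index: FragmentIndex) -> bool:
    for length in index.fragment_lengths:
        for i in range(len(seq) - length + 1):
            if index.lookup(seq[i : i + length]) is not None:
                return True
    return False


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def simulate_reads(spec: SimulationSpec) -> SimulationResult:
    """Generate reads plus a truth table, reproducibly from `spec.seed`."""
    rng = np.random.default_rng(spec.seed)
    cds = spec.reference.cds
    fragment_sets = [
        build_site_fragments(
            spec.reference,
            site.record,
            spec.fragment_length,
            native_position=site.native_position,
        )
        for site in spec.sites
    ]
    index = build_fragment_index(fragment_sets) if fragment_sets else None
    background = (
        shuffle_background(cds, rng, index) if spec.background_fraction > 0 else None
    )
    codon_choices = [
        [site.mutant_codon or site.record.mutant_codon]
        if (site.mutant_codon or site.record.mutant_codon)
        else codons_for(site.record.mutant_aa)
        for site in spec.sites
    ]
    qual = tuple([spec.base_quality] * spec.read_length)
    reads: list[ReadRecord] = []
    rows = []
    span = len(cds) - spec.read_length + 1
    for i in range(spec.n_reads):
        read_id = f"read{i:06d}"
        is_background = rng.random() < spec.background_fraction
        row: dict[str, object] = {"read_id": read_id}
        if is_background:
            source = background
            row["origin"] = "background"
            for fs in fragment_sets:
                row[f"allele:{fs.site_id}"] = ""
                row[f"covers:{fs.site_id}"] = False
        else:
            row["origin"] = "ace"
            resistant_flags = [
                rng.random() < site.resistant_frequency for site in spec.sites
            ]
            if any(resistant_flags):
                hap = list(cds)
                for flag, site, choices, fs in zip(
                    resistant_flags, spec.sites, codon_choices, fragment_sets
                ):
                    if flag:
                        codon = choices[rng.integers(len(choices))]
                        start = 3 * (fs.cds_codon_index - 1)
                        hap[start : start + 3] = codon
                source = "".join(hap)
            else:
                source = cds
            for flag, fs in zip(resistant_flags, fragment_sets):
                row[f"allele:{fs.site_id}"] = "resistant" if flag else "susceptible"
        start = int(rng.integers(span))
        if not is_background:
            for fs in fragment_sets:
                ws, we = fs.cds_window
                row[f"covers:{fs.site_id}"] = start + 1 <= ws and start + spec.read_length >= we
        seq = source[start : start + spec.read_length]
        seq = _apply_errors(seq, spec.error_rate, rng)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(ReadRecord(read_id=read_id, sequence=seq, qualities=qual))
        rows.append(row)
    truth = pd.DataFrame(rows)
    return SimulationResult(reads=reads, truth=truth, fragment_sets=fragment_sets)


_AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def synthetic_reference(
    seed: int = 0,
    n_codons: int = 600,
    species: str = "Synthetica exempli",
    gene: str = "ace1",
    accession: str = "SYN1",
    required_residues: dict[int, str] | None = None,
) -> AceReference:
    """A synthetic ace-like reference: random CDS whose translation carries
    the two conserved AChE motifs (WIYGGG, FGESAE) and any residues required
    at given 1-based positions (e.g. the wild-type glycine of a G->S site).

    Synthetic stand-in for demos and tests; not a real gene.
    """
    if n_codons < 300:
        raise ValueError("n_codons must be >= 300 (motif offsets are fixed)")
    rng = np.random.default_rng(seed)
    protein = [str(a) for a in rng.choice(_AA20, size=n_codons)]
    protein[80:86] = "WIYGGG"
    protein[230:236] = "FGESAE"
    for pos, aa in (required_residues or {}).items():
        if 81 <= pos <= 86 or 231 <= pos <= 236:
            raise ValueError(f"position {pos} overlaps a conserved motif")
        protein[pos - 1] = aa
    codons = []
    for aa in protein:
        options = codons_for(aa)
        codons.append(options[rng.integers(len(options))])
    codons.append("TAA")
    return AceReference(
        species=species,
        gene=gene,
        accession=accession,
        cds="".join(codons),
        protein="".join(protein),
    )


def truth_resistant_fraction(truth: pd.DataFrame, site_id: str) -> float | None:
    """Resistant proportion among reads that fully cover the site window."""
    covering = truth[truth[f"covers:{site_id}"] == True]  # noqa: E712
    if covering.empty:
        return None
    return float((covering[f"allele:{site_id}"] == "resistant").mean())


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            if read.qualities is None:
                raise ValueError(f"{read.read_id}: FASTQ needs qualities")
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
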