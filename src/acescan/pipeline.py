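"""End-to-end orchestration: references + profile + reads -> site report.

Stages: load references -> validate profile -> build fragments -> QC ->
pre-filter -> scan -> count -> report.  Outputs are a per-site TSV (stable,
byte-identical across re-runs on identical inputs) and a JSON run report
(parameters, QC, stage tallies, timestamp).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_K,
    DEFAULT_MIN_SHARED_KMERS,
    DEFAULT_Q30_THRESHOLD,
    QcReport,
    SiteCounts,
    compute_q30,
    count_sites,
    read_any,
    scan_read,
)
from .fragments import (
    DEFAULT_FRAGMENT_LENGTH,
    FragmentSet,
    build_fragment_index,
    build_site_fragments,
    write_fragments_tsv,
)
from .profile import (
    MutationProfile,
    bundled_profile,
    load_profile,
    resolve_native_position,
)
from .reference import (
    AceReference,
    build_position_map,
    global_align,
    load_protein,
    load_reference,
)

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "site_id",
    "species",
    "gene",
    "mutation_name",
    "susceptible_reads",
    "resistant_reads",
    "ambiguous_reads",
    "resistance_frequency",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    species: str
    genes: tuple[str, ...]
    reference_paths: dict[str, str]  # gene -> FASTA path
    reads_path: str
    output_dir: str
    profile_path: str | None = None  # None -> bundled profile
    torpedo_path: str | None = None  # needed when records lack native positions
    reads_format: str = "auto"
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    k: int = DEFAULT_K
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS
    q30_threshold: float = DEFAULT_Q30_THRESHOLD
    strict_qc: bool = False
    min_cds_length: int = 1800
    require_motifs: bool = True
    reference_record_ids: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        missing = [p for p in self._paths() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input file(s): {missing}")
        unknown = [g for g in self.genes if g not in ("ace1", "ace2")]
        if unknown:
            raise PipelineError(f"unknown gene(s): {unknown}")
        for gene in self.genes:
            if gene not in self.reference_paths:
                raise PipelineError(f"no reference FASTA for {gene}")
        if not 0.0 <= self.q30_threshold <= 1.0:
            raise PipelineError("q30_threshold must be in [0, 1]")

    def _paths(self) -> list[str]:
        paths = [self.reads_path, *self.reference_paths.values()]
        if self.profile_path:
            paths.append(self.profile_path)
        if self.torpedo_path:
            paths.append(self.torpedo_path)
        return paths


@dataclass
class RunResult:
    site_counts: list[SiteCounts]
    fragment_sets: list[FragmentSet]
    qc: QcReport
    n_reads_total: int
    n_reads_prefiltered: int
    sites_tsv: Path
    report_json: Path
    table: pd.DataFrame


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"stage {name!r}: {exc}")

    return wrap


def build_fragments_for_run(
    references: dict[str, AceReference],
    profile: MutationProfile,
    config: RunConfig,
) -> tuple[list[FragmentSet], dict[str, str]]:
    """Fragment sets for every profile record matching the run's species and
    genes; Torpedo-only records are resolved through a position map."""
    torpedo = load_protein(config.torpedo_path) if config.torpedo_path else None
    maps: dict[str, object] = {}
    fragment_sets: list[FragmentSet] = []
    site_to_name: dict[str, str] = {}
    for gene, reference in references.items():
        records = profile.subset(species=config.species, gene=gene).records
        if not records:
            logger.warning("no profile records for %s %s", config.species, gene)
        for record in records:
            if record.native_position is None:
                if torpedo is None:
                    raise PipelineError(
                        f"record {record.name} has no native position and no "
                        f"Torpedo reference FASTA was supplied"
                    )
                if gene not in maps:
                    alignment = global_align(reference.protein, torpedo)
                    maps[gene] = build_position_map(alignment, config.species, gene)
                native = resolve_native_position(record, maps[gene])
            else:
                native = record.native_position
            fs = build_site_fragments(
                reference, record, config.fragment_length, native_position=native
            )
            fragment_sets.append(fs)
            site_to_name[fs.site_id] = record.name
    return fragment_sets, site_to_name


def sites_table(
    site_counts: list[SiteCounts],
    fragment_sets: list[FragmentSet],
    site_to_name: dict[str, str],
) -> pd.DataFrame:
    meta = {fs.site_id: fs for fs in fragment_sets}
    rows = []
    for sc in sorted(site_counts, key=lambda s: s.site_id):
        fs = meta[sc.site_id]
        freq = sc.resistance_frequency
        rows.append(
            {
                "site_id": sc.site_id,
                "species": fs.species,
                "gene": fs.gene,
                "mutation_name": site_to_name.get(sc.site_id, fs.mutation_name),
                "susceptible_reads": sc.susceptible_reads,
                "resistant_reads": sc.resistant_reads,
                "ambiguous_reads": sc.ambiguous_reads,
                "resistance_frequency": "NA" if freq is None else f"{freq:.6f}",
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write sites.tsv + report.json."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    references: dict[str, AceReference] = {}
    for gene in config.genes:
        try:
            references[gene] = load_reference(
                config.reference_paths[gene],
                gene,
                config.species,
                record_id=config.reference_record_ids.get(gene),
                min_cds_length=config.min_cds_length,
                require_motifs=config.require_motifs,
            )
        except Exception as exc:
            raise _stage("load_reference")(exc) from exc

    try:
        profile = (
            load_profile(config.profile_path) if config.profile_path else bundled_profile()
        )
    except Exception as exc:
        raise _stage("load_profile")(exc) from exc

    try:
        fragment_sets, site_to_name = build_fragments_for_run(
            references, profile, config
        )
        if not fragment_sets:
            raise PipelineError(
                f"profile has no records for species {config.species!r} "
                f"and genes {config.genes}"
            )
        index = build_fragment_index(fragment_sets)
    except PipelineError:
        raise
    except Exception as exc:
        raise _stage("build_fragments")(exc) from exc

    try:
        reads = list(read_any(config.reads_path, config.reads_format))
        if not reads:
            raise PipelineError(f"no reads in {config.reads_path}")
        qc = compute_q30(reads, config.q30_threshold)
    except PipelineError:
        raise
    except Exception as exc:
        raise _stage("qc")(exc) from exc
    if not qc.computable:
        logger.warning("qualities unavailable; Q30 not computed")
    elif not qc.passed:
        msg = f"Q30 fraction {qc.q30_fraction:.3f} below threshold {qc.threshold}"
        if config.strict_qc:
            raise PipelineError(f"stage 'qc': {msg}")
        logger.warning("%s; continuing (strict_qc off)", msg)

    from .classify import prefilter_reads  # local import keeps module surface flat

    kept = list(
        prefilter_reads(reads, references.values(), config.k, config.min_shared_kmers)
    )
    logger.info("pre-filter: %d/%d reads retained", len(kept), len(reads))

    site_counts = count_sites(
        (scan_read(r, index) for r in kept), site_ids=index.site_ids
    )

    table = sites_table(site_counts, fragment_sets, site_to_name)
    sites_tsv = out_dir / "sites.tsv"
    table.to_csv(sites_tsv, sep="\t", index=False)
    write_fragments_tsv(fragment_sets, out_dir / "fragments.tsv")

    report = {
        "acescan_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            "species": config.species,
            "genes": list(config.genes),
            "reference_paths": config.reference_paths,
            "profile": config.profile_path or "bundled",
            "profile_version": profile.version,
            "reads_path": config.reads_path,
            "fragment_length": config.fragment_length,
            "k": config.k,
            "min_shared_kmers": config.min_shared_kmers,
            "q30_threshold": config.q30_threshold,
        },
        "qc": {
            "total_reads": qc.total_reads,
            "total_bases": qc.total_bases,
            "q30_fraction": qc.q30_fraction,
            "computable": qc.computable,
            "passed": qc.passed,
        },
        "stages": {
            "reads_in": len(reads),
            "reads_after_prefilter": len(kept),
            "sites": len(site_counts),
        },
        "sites": [
            {
                "site_id": sc.site_id,
                "mutation_name": site_to_name.get(sc.site_id, ""),
                "susceptible_reads": sc.susceptible_reads,
                "resistant_reads": sc.resistant_reads,
                "ambiguous_reads": sc.ambiguous_reads,
                "resistance_frequency": sc.resistance_frequency,
            }
            for sc in sorted(site_counts, key=lambda s: s.site_id)
        ],
    }
    report_json = out_dir / "report.json"
    report_json.write_text(json.dumps(report, indent=2) + "\n")

    return RunResult(
        site_counts=site_counts,
        fragment_sets=fragment_sets,
        qc=qc,
        n_reads_total=len(reads),
        n_reads_prefiltered=len(kept),
        sites_tsv=sites_tsv,
        report_json=report_json,
        table=table,
    )


def summarize_runs(report_paths: list[str | Path]) -> pd.DataFrame:
    """Combine per-sample JSON reports into one long-format table.

    Rows are (sample, site); sites absent from a sample appear with NA
    counts.  Mixing reports from different profile versions is an error.
    """
    if not report_paths:
        raise ValueError("no reports")
    reports = []
    for path in report_paths:
        with open(path) as fh:
            reports.append((Path(path), json.load(fh)))
    versions = {r["config"].get("profile_version") for _, r in reports}
    if len(versions) > 1:
        raise ValueError(f"mixed profile versions: {sorted(map(str, versions))}")
    all_sites = sorted({s["site_id"] for _, r in reports for s in r["sites"]})
    rows = []
    for path, rep in reports:
        sample = path.parent.name or path.stem
        by_site = {s["site_id"]: s for s in rep["sites"]}
        for site_id in all_sites:
            s = by_site.get(site_id)
            rows.append(
                {
                    "sample": sample,
                    "site_id": site_id,
                    "mutation_name": s["mutation_name"] if s else "NA",
                    "susceptible_reads": s["susceptible_reads"] if s else "NA",
                    "resistant_reads": s["resistant_reads"] if s else "NA",
                    "ambiguous_reads": s["ambiguous_reads"] if s else "NA",
                    "resistance_frequency": (
                        "NA"
                        if s is None or s["resistance_frequency"] is None
                        else f"{s['resistance_frequency']:.6f}"
                    ),
                }
            )
    return pd.DataFrame(rows)
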