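"""End-to-end analysis pipeline: ingest -> collapse -> stats -> filter -> profile -> clone.

One :class:`PipelineConfig` drives the full analysis and every intermediate is
written to the output directory, so a figure-producing run is reproducible
from its persisted resolved config alone.  Identical config + inputs give a
byte-identical output bundle (the manifest carries a config hash, versions,
per-stage record counts and per-file checksums; wall-clock timestamps go to
the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import airr_io, clonal_inference, mutation_profiling, repertoire_stats
from .airr_io import RearrangementSet
from .errors import IdiorepError
from .mutation_profiling import HotspotScheme
from .synthetic_data import germline_reference

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serializable to/from JSON."""

    input_tsv: str | None = None
    germline_fasta: str | None = None
    region_bounds_json: str | None = None
    out_dir: str = "idiorep_out"
    # filtering for the idiotope analysis arm
    v_gene_prefix: str = "IGHV4-34"
    isotype: str | None = None
    productive_only: bool = True
    # profiling
    identity_floor: float = 0.70
    include_aux_in_avy: bool = False
    # clonal inference
    distance_threshold: float = 0.15
    linkage: str = "single"
    edge_rule: int = 1
    sample_n: int | None = None
    seed: int = 0
    # repertoire statistics
    chao1_variant: str = "bias_corrected"
    chao1_on: str = "junction"
    usage_weighting: str = "clone"
    include_nonproductive_usage: bool = True
    trim_anchors: bool = True
    hydrophobicity_scale: str = "kyte-doolittle"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ReportBundle:
    """Paths and in-memory tables produced by one pipeline run."""

    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    files: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(bundle: ReportBundle, name: str, df: pd.DataFrame) -> None:
    path = bundle.out_dir / f"{name}.tsv"
    df.to_csv(path, sep="\t", index=False)
    bundle.tables[name] = df
    bundle.files[name] = path


def run_pipeline(
    config: PipelineConfig, rset: RearrangementSet | None = None
) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Stages (fixed order): read, collapse, repertoire statistics on the
    collapsed set, filter to the V gene of interest, mutation profiling and
    idiotope classification, clonal grouping, connectivity graph (optionally
    on a seeded subsample of clone groups), and top-clone enumeration.
    ``rset`` may be passed directly instead of ``config.input_tsv``.

    Raises :class:`IdiorepError` subclasses with the failing stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    stage_counts: dict[str, int] = {}
    stage = "read"
    try:
        if rset is None:
            if config.input_tsv is None:
                raise IdiorepError("no input: set input_tsv or pass a RearrangementSet")
            rset = airr_io.read_rearrangements(config.input_tsv)
        stage_counts["read"] = len(rset)
        logger.info("stage=read records=%d", len(rset))

        stage = "collapse"
        collapsed = airr_io.collapse_transcripts(rset)
        stage_counts["collapse"] = len(collapsed)
        logger.info("stage=collapse records=%d", len(collapsed))

        stage = "repertoire_stats"
        diversity_rows = []
        for subject, sub_df in collapsed.df.groupby("subject_id"):
            sub = RearrangementSet(sub_df)
            # after collapsing, duplicate_count carries the original abundance
            est = repertoire_stats.repertoire_chao1(
                sub, variant=config.chao1_variant, on=config.chao1_on,
                weighting="duplicate",
            )
            diversity_rows.append(
                {
                    "subject_id": subject,
                    "s_obs": est.s_obs,
                    "f1": est.f1,
                    "f2": est.f2,
                    "chao1": est.chao1,
                    "variant": est.variant,
                }
            )
        _write(bundle, "diversity", pd.DataFrame(diversity_rows))
        usage = repertoire_stats.vj_usage_matrix(
            collapsed,
            include_nonproductive=config.include_nonproductive_usage,
            weighting=config.usage_weighting,
        )
        _write(bundle, "vj_usage", usage.long())
        lengths = repertoire_stats.cdr3_length_by_j(collapsed, trim_anchors=config.trim_anchors)
        _write(bundle, "cdr3_lengths", lengths.to_frame())
        physchem = repertoire_stats.cdr3_physicochemistry(
            collapsed, scale=config.hydrophobicity_scale, trim_anchors=config.trim_anchors
        )
        _write(bundle, "physchem_subjects", physchem.per_subject)
        distal, j_usage = repertoire_stats.distal_j_fraction(
            collapsed, weighting=config.usage_weighting
        )
        _write(
            bundle,
            "j_usage",
            j_usage.rename("fraction").reset_index().rename(columns={"index": "j_gene"}),
        )
        bundle.manifest["distal_j_fraction"] = distal

        stage = "filter"
        filtered = airr_io.filter_rearrangements(
            collapsed,
            v_gene_prefix=config.v_gene_prefix,
            isotype=config.isotype,
            productive_only=config.productive_only,
        )
        stage_counts["filter"] = len(filtered)
        logger.info("stage=filter records=%d", len(filtered))

        stage = "profile"
        if config.germline_fasta and config.region_bounds_json:
            germlines = airr_io.read_germline_reference(
                config.germline_fasta, config.region_bounds_json
            )
            germlines = {ref.gene: ref for ref in germlines.values()}
        else:
            germlines = {config.v_gene_prefix: germline_reference(config.v_gene_prefix)}
        scheme = HotspotScheme(include_aux_in_avy=config.include_aux_in_avy)
        profiled_df = mutation_profiling.profile_set(
            filtered, germlines, scheme, identity_floor=config.identity_floor
        )
        profiled = filtered.with_df(profiled_df, "profiled against germline")
        category_table = mutation_profiling.summarize_categories(profiled_df)
        _write(bundle, "category_table", category_table)

        stage = "clone"
        groups = clonal_inference.group_clones(
            profiled,
            distance_threshold=config.distance_threshold,
            linkage=config.linkage,
        )
        stage_counts["clone_groups"] = len(groups)
        assignments = clonal_inference.assign_clones(profiled, groups)
        _write(bundle, "clone_assignments", assignments)

        stage = "graph"
        graph_groups = groups
        if config.sample_n is not None:
            graph_groups = clonal_inference.sample_groups(
                groups, config.sample_n, config.seed
            )
        graph = clonal_inference.build_connectivity_graph(
            graph_groups, profiled, edge_rule=config.edge_rule
        )
        for path in clonal_inference.export_graph(graph, out_dir):
            bundle.files[path.stem] = path

        stage = "topclones"
        top = clonal_inference.enumerate_top_clones(profiled, n=10)
        _write(bundle, "top_clones", top.df)
    except IdiorepError as exc:
        partial = {"failed_stage": stage, "stage_counts": stage_counts, "error": str(exc)}
        (out_dir / "manifest.json").write_text(json.dumps(partial, indent=1))
        raise

    stage_counts["graph_groups"] = len(graph_groups)
    # out_dir is a location, not an analysis parameter: keep it out of the
    # hash so identical analyses in different directories hash identically
    hashed = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    config_json = json.dumps(hashed, sort_keys=True)
    bundle.manifest.update(
        {
            "idiorep_version": __version__,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "stage_counts": stage_counts,
            "files": {
                name: {"path": path.name, "sha256": _sha256(path)}
                for name, path in sorted(bundle.files.items())
            },
        }
    )
    (out_dir / "resolved_config.json").write_text(config_json)
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    bundle.files["manifest"] = out_dir / "manifest.json"
    return bundle
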