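"""Repertoire-level skew statistics: Chao1 diversity, V-J usage, CDR3 features.

Impaired V(D)J recombination leaves characteristic fingerprints on a
repertoire: reduced clonal richness, skewed V-J segment pairing (a bias toward
efficient recombination-signal sequences), loss of the distal J segments
(JH5/JH6), and shifts in CDR3 length and physicochemistry.  This module
computes those summaries from a rearrangement set.

Chao1 estimates true clonotype richness from the abundance of rare species:

    classic          S_chao1 = S_obs + f1^2 / (2 f2)
    bias-corrected   S_chao1 = S_obs + f1 (f1 - 1) / (2 (f2 + 1))

where f1/f2 are the singleton/doubleton counts.  The classic form is undefined
when f2 = 0 and falls back to the bias-corrected form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .airr_io import RearrangementSet, gene_from_call
from .errors import EstimateError, ValidationError

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kyte-doolittle": dict(KYTE_DOOLITTLE),
}

DEFAULT_DISTAL_GENES = frozenset({"IGHJ5", "IGHJ6"})


@dataclass(frozen=True)
class DiversityEstimate:
    """Chao1 richness components for one abundance vector."""

    s_obs: int
    f1: int
    f2: int
    chao1: float
    variant: str  # "classic" | "bias_corrected"


def chao1_estimate(abundances, variant: str = "bias_corrected") -> DiversityEstimate:
    """Chao1 richness from a vector of per-clonotype abundances (all >= 1)."""
    if variant not in ("classic", "bias_corrected"):
        raise ValidationError(f"unknown Chao1 variant: {variant}")
    values = np.asarray(list(abundances))
    if values.size == 0:
        raise EstimateError("Chao1 is undefined for an empty abundance vector")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValidationError("abundances must be integers")
        values = np.round(values).astype(int)
    if (values < 1).any():
        raise ValidationError("abundances must be >= 1")
    s_obs = int(values.size)
    f1 = int((values == 1).sum())
    f2 = int((values == 2).sum())
    used = variant
    if variant == "classic" and f2 == 0:
        used = "bias_corrected"  # classic form undefined; documented fallback
    if used == "classic":
        chao1 = s_obs + f1 * f1 / (2 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return DiversityEstimate(s_obs=s_obs, f1=f1, f2=f2, chao1=float(chao1), variant=used)


def _clone_abundances(rset: RearrangementSet, on: str, weighting: str) -> list[int]:
    df = rset.df
    key = df[on].astype(str)
    mask = key.str.len() > 0
    if weighting == "duplicate":
        weights = pd.to_numeric(df.loc[mask, "duplicate_count"], errors="coerce").fillna(1)
        counts = weights.groupby(key[mask]).sum()
    else:
        counts = key[mask].value_counts()
    return [int(c) for c in counts]


def repertoire_chao1(
    rset: RearrangementSet,
    variant: str = "bias_corrected",
    on: str = "junction",
    weighting: str = "record",
) -> DiversityEstimate:
    """Chao1 over unique CDR3 sequences of a set.

    ``on`` selects the clonotype key: ``junction`` (nucleotide, default) or
    ``junction_aa``.  ``weighting="duplicate"`` uses duplicate_count as the
    abundance; the default counts records (appropriate after collapsing).
    """
    if on not in ("junction", "junction_aa"):
        raise ValidationError(f"unsupported clonotype key: {on}")
    abundances = _clone_abundances(rset, on, weighting)
    if not abundances:
        raise EstimateError("no records with a usable clonotype key")
    return chao1_estimate(abundances, variant)


@dataclass
class VJUsageMatrix:
    """V x J pairing usage as percentages of all pairs (sums to 100)."""

    matrix: pd.DataFrame  # rows: V genes, cols: J genes, cells: percent
    include_nonproductive: bool
    n_pairs: int

    def long(self) -> pd.DataFrame:
        out = self.matrix.stack().rename("percent").reset_index()
        out.columns = ["v_gene", "j_gene", "percent"]
        return out


def vj_usage_matrix(
    rset: RearrangementSet,
    include_nonproductive: bool = True,
    weighting: str = "clone",
) -> VJUsageMatrix:
    """Percentage usage of every V x J gene pair.

    Non-productive rearrangements are included by default: they never saw
    antigen selection, so their segment usage reads out recombination-signal
    preference directly.  ``weighting="clone"`` (default) counts each unique
    (V, J, junction) clonotype once; ``"record"`` counts rows,
    ``"duplicate"`` weights by duplicate_count.
    """
    df = rset.df
    if not include_nonproductive:
        df = df[df["productive"].map(lambda v: str(v).upper() in ("TRUE", "T", "1"))]
    if df.empty:
        raise EstimateError("cannot compute V-J usage of an empty set")
    v = df["v_call"].map(gene_from_call)
    j = df["j_call"].map(gene_from_call)
    if weighting == "clone":
        work = pd.DataFrame(
            {"v": v.to_numpy(), "j": j.to_numpy(), "junction": df["junction"].astype(str).to_numpy()}
        ).drop_duplicates()
        counts = work.groupby(["v", "j"]).size()
    elif weighting == "duplicate":
        weights = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1)
        counts = weights.groupby([v.to_numpy(), j.to_numpy()]).sum()
    elif weighting == "record":
        counts = pd.Series(1, index=df.index).groupby([v.to_numpy(), j.to_numpy()]).sum()
    else:
        raise ValidationError(f"unknown weighting: {weighting}")
    total = counts.sum()
    matrix = (100.0 * counts / total).unstack(fill_value=0.0)
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "v_gene"
    matrix.columns.name = "j_gene"
    return VJUsageMatrix(matrix=matrix, include_nonproductive=include_nonproductive, n_pairs=int(total))


@dataclass
class LengthDistributionTable:
    """Per-J-gene histogram of CDR3 amino-acid lengths."""

    per_j: dict[str, Counter]
    trim_anchors: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"j_gene": j, "cdr3_length": length, "count": count}
            for j in sorted(self.per_j)
            for length, count in sorted(self.per_j[j].items())
        ]
        return pd.DataFrame(rows, columns=["j_gene", "cdr3_length", "count"])


def cdr3_length_by_j(
    rset: RearrangementSet, trim_anchors: bool = True
) -> LengthDistributionTable:
    """CDR3 aa length histograms split by J gene.

    CDR3 length defaults to |junction_aa| - 2: the junction includes the
    conserved Cys-104 and Trp/Phe-118 anchors, which are not part of CDR3.
    Junctions shorter than the anchors are excluded and tallied in provenance.
    """
    trim = 2 if trim_anchors else 0
    per_j: dict[str, Counter] = {}
    excluded = 0
    for j_call, junction_aa in zip(rset.df["j_call"], rset.df["junction_aa"]):
        aa = str(junction_aa)
        if not aa:
            continue
        if len(aa) <= trim:
            excluded += 1
            continue
        per_j.setdefault(gene_from_call(str(j_call)), Counter())[len(aa) - trim] += 1
    if excluded:
        rset.provenance.append(f"cdr3_length_by_j: {excluded} junctions shorter than anchors excluded")
    return LengthDistributionTable(per_j=per_j, trim_anchors=trim_anchors)


@dataclass
class PhysChemTable:
    """Per-CDR3 hydrophobicity and cysteine content with per-subject aggregates."""

    per_record: pd.DataFrame
    per_subject: pd.DataFrame
    scale: str


def cdr3_physicochemistry(
    rset: RearrangementSet,
    scale: str = "kyte-doolittle",
    trim_anchors: bool = True,
) -> PhysChemTable:
    """Mean residue hydrophobicity and cysteine count of each trimmed CDR3.

    The default scale is Kyte-Doolittle (GRAVY-style mean over residues).
    Records with unknown residue letters are flagged (``valid`` = False) and
    excluded from per-subject means; per-subject aggregates report the mean
    hydrophobicity and the fraction of CDR3s containing at least one cysteine.
    """
    if scale not in HYDROPHOBICITY_SCALES:
        raise ValidationError(f"unknown hydrophobicity scale: {scale}")
    table = HYDROPHOBICITY_SCALES[scale]
    trim = 2 if trim_anchors else 0
    rows = []
    for sid, subject, junction_aa in zip(
        rset.df["sequence_id"], rset.df["subject_id"], rset.df["junction_aa"]
    ):
        aa = str(junction_aa)
        if len(aa) <= trim:
            continue
        cdr3 = aa[trim // 2 : len(aa) - trim // 2] if trim else aa
        valid = all(r in table for r in cdr3)
        rows.append(
            {
                "sequence_id": sid,
                "subject_id": str(subject),
                "cdr3_aa": cdr3,
                "cdr3_length": len(cdr3),
                "mean_hydrophobicity": (
                    float(np.mean([table[r] for r in cdr3])) if valid else np.nan
                ),
                "n_cysteine": cdr3.count("C"),
                "valid": valid,
            }
        )
    per_record = pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "subject_id", "cdr3_aa", "cdr3_length",
            "mean_hydrophobicity", "n_cysteine", "valid",
        ],
    )
    if per_record.empty:
        per_subject = pd.DataFrame(
            columns=["subject_id", "n", "mean_hydrophobicity", "frac_with_cysteine"]
        )
    else:
        ok = per_record[per_record["valid"]]
        per_subject = (
            ok.groupby("subject_id")
            .agg(
                n=("sequence_id", "size"),
                mean_hydrophobicity=("mean_hydrophobicity", "mean"),
                frac_with_cysteine=("n_cysteine", lambda s: float((s > 0).mean())),
            )
            .reset_index()
        )
    return PhysChemTable(per_record=per_record, per_subject=per_subject, scale=scale)


def distal_j_fraction(
    rset: RearrangementSet,
    distal_genes: frozenset[str] | set[str] = DEFAULT_DISTAL_GENES,
    weighting: str = "clone",
) -> tuple[float, pd.Series]:
    """Fraction of rearrangements using a distal J segment, plus per-J usage.

    Distal JH5/JH6 loss is a recombination-efficiency signature.  Returns the
    distal fraction and the full per-J usage vector (sums to 1).  Weighting as
    in :func:`vj_usage_matrix`.
    """
    df = rset.df
    if df.empty:
        raise EstimateError("cannot compute distal J usage of an empty set")
    j = df["j_call"].map(gene_from_call)
    if weighting == "clone":
        work = pd.DataFrame(
            {"j": j.to_numpy(), "v": df["v_call"].map(gene_from_call).to_numpy(),
             "junction": df["junction"].astype(str).to_numpy()}
        ).drop_duplicates()
        counts = work.groupby("j").size()
    elif weighting == "duplicate":
        weights = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1)
        counts = weights.groupby(j.to_numpy()).sum()
    elif weighting == "record":
        counts = j.value_counts()
    else:
        raise ValidationError(f"unknown weighting: {weighting}")
    usage = (counts / counts.sum()).sort_index()
    fraction = float(usage.reindex(sorted(distal_genes), fill_value=0.0).sum())
    return fraction, usage
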