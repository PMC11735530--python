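"""Read, validate, collapse and filter AIRR rearrangement tables and germline references.

The canonical on-disk format is the AIRR Rearrangement TSV dialect: one row per
sequenced receptor transcript, column names following the AIRR schema
(``sequence_id``, ``sequence``, ``v_call``, ``j_call``, ``c_call``, ``junction``,
``junction_aa``, ``productive``, ``duplicate_count``, ...).  Unknown columns are
carried through untouched.  In memory a :class:`RearrangementSet` wraps a pandas
DataFrame plus a provenance log of the filters applied to it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import SchemaError, ValidationError

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "junction")
SEQUENCE_COLUMNS = ("sequence", "sequence_alignment")

#: Default keys used to collapse transcripts into unique records.  Isotype
#: (c_call) stays in the keys so IgM/IgG copies of one heavy chain remain
#: distinct, matching how per-isotype tallies are reported downstream.
DEFAULT_COLLAPSE_KEYS = ("sequence", "c_call", "subject_id", "subset_label")

KNOWN_ISOTYPES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")

_REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


def gene_from_call(call: str) -> str:
    """Reduce an IMGT-style V/J/C call to its gene-level name.

    ``"IGHV4-34*01"`` -> ``"IGHV4-34"``; comma-separated multi-assignments keep
    the first call (the ambiguity is recorded by the reader in ``call_ambiguous``).
    """
    if not isinstance(call, str) or not call:
        return ""
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def _gene_matches_prefix(call: str, prefix: str) -> bool:
    gene = gene_from_call(call)
    if gene == prefix:
        return True
    return bool(re.match(re.escape(prefix) + r"[-/]", gene))


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string in frame 1 (trailing partial codon dropped)."""
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    return str(Seq(nt).translate())


def infer_productive(junction_nt: str) -> bool:
    """Minimal productivity rule: junction in frame and stop-codon free."""
    if not isinstance(junction_nt, str) or not junction_nt:
        return False
    if len(junction_nt) % 3 != 0:
        return False
    return "*" not in translate_nt(junction_nt)


@dataclass
class RearrangementSet:
    """An ordered collection of rearrangement records with provenance.

    ``df`` holds one row per record using AIRR column names; ``provenance``
    accumulates a human-readable log of the source path and every filter or
    collapse applied.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def with_df(self, df: pd.DataFrame, note: str | None = None) -> "RearrangementSet":
        log = list(self.provenance)
        if note:
            log.append(note)
        return RearrangementSet(df.reset_index(drop=True), log)

    @property
    def v_genes(self) -> pd.Series:
        return self.df["v_call"].map(gene_from_call)

    @property
    def j_genes(self) -> pd.Series:
        return self.df["j_call"].map(gene_from_call)


@dataclass(frozen=True)
class GermlineReference:
    """A germline V-gene reference with framework/CDR bounds.

    ``region_bounds`` maps FR1/CDR1/FR2/CDR2/FR3 to 1-based inclusive
    amino-acid intervals on ``sequence_aa`` (the frame-1 translation of
    ``sequence_nt``).
    """

    allele_name: str
    sequence_nt: str
    region_bounds: Mapping[str, tuple[int, int]]

    @property
    def sequence_aa(self) -> str:
        return translate_nt(self.sequence_nt)

    @property
    def gene(self) -> str:
        return gene_from_call(self.allele_name)

    def region_of(self, aa_position: int) -> str | None:
        for name, (lo, hi) in self.region_bounds.items():
            if lo <= aa_position <= hi:
                return name
        return None

    def validate(self) -> None:
        aa = self.sequence_aa
        prev_end = 0
        for name in _REGION_ORDER:
            if name not in self.region_bounds:
                continue
            lo, hi = self.region_bounds[name]
            if lo <= prev_end:
                raise ValidationError(
                    f"{self.allele_name}: region {name} [{lo},{hi}] overlaps or "
                    f"precedes the previous region"
                )
            if hi < lo or hi > len(aa):
                raise ValidationError(
                    f"{self.allele_name}: region {name} interval [{lo},{hi}] "
                    f"outside protein length {len(aa)}"
                )
            prev_end = hi


def _parse_bool(value) -> bool | None:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().upper()
    if text in ("T", "TRUE", "1"):
        return True
    if text in ("F", "FALSE", "0"):
        return False
    return None


def read_rearrangements(path: str | Path, strict: bool = False) -> RearrangementSet:
    """Read an AIRR rearrangement TSV into a :class:`RearrangementSet`.

    Required columns: sequence_id, v_call, j_call, junction and one of
    sequence / sequence_alignment.  Missing optional columns receive
    documented defaults: ``duplicate_count`` = 1, ``productive`` inferred from
    the junction frame, ``locus`` from the v_call prefix.  Multi-allele v_call
    assignments keep the first call and set ``call_ambiguous``.

    Raises
    ------
    SchemaError
        if a required column is absent (the message names the column).
    ValidationError
        in strict mode, on duplicate sequence_id or locus-inconsistent calls.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col}")
    if not any(c in df.columns for c in SEQUENCE_COLUMNS):
        raise SchemaError("required column missing: sequence (or sequence_alignment)")
    if "sequence" not in df.columns:
        df["sequence"] = df["sequence_alignment"].str.replace(".", "", regex=False)

    ambiguous = df["v_call"].str.contains(",", regex=False)
    if ambiguous.any():
        df["call_ambiguous"] = ambiguous.map({True: "T", False: "F"})
        df["v_call"] = df["v_call"].str.split(",").str[0].str.strip()

    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    else:
        df["duplicate_count"] = (
            pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1).astype(int)
        )
    if (df["duplicate_count"] < 1).any():
        raise ValidationError("duplicate_count must be >= 1")

    if "junction_aa" not in df.columns:
        df["junction_aa"] = df["junction"].map(
            lambda j: translate_nt(j) if j and len(j) % 3 == 0 else ""
        )
    if "productive" in df.columns:
        parsed = df["productive"].map(_parse_bool)
        inferred = df["junction"].map(infer_productive)
        df["productive"] = [p if p is not None else i for p, i in zip(parsed, inferred)]
    else:
        df["productive"] = df["junction"].map(infer_productive)

    if "locus" not in df.columns:
        df["locus"] = df["v_call"].str[:3].str.upper()
    for col in ("c_call", "subject_id", "subset_label"):
        if col not in df.columns:
            df[col] = ""

    if strict:
        dup = df["sequence_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate sequence_id: {df.loc[dup, 'sequence_id'].iloc[0]}"
            )
        bad = ~df.apply(
            lambda r: str(r["v_call"]).upper().startswith(str(r["locus"]).upper()),
            axis=1,
        )
        if bad.any():
            raise ValidationError(
                f"v_call inconsistent with locus for sequence_id "
                f"{df.loc[bad, 'sequence_id'].iloc[0]}"
            )

    return RearrangementSet(df, [f"read {len(df)} records from {path}"])


def write_rearrangements(rset: RearrangementSet, path: str | Path) -> Path:
    """Write a set back to AIRR TSV; booleans serialized as T/F."""
    path = Path(path)
    out = rset.df.copy()
    if "productive" in out.columns:
        out["productive"] = out["productive"].map(
            lambda v: "T" if _parse_bool(v) else "F"
        )
    out.to_csv(path, sep="\t", index=False)
    return path


def collapse_transcripts(
    rset: RearrangementSet, keys: Sequence[str] = DEFAULT_COLLAPSE_KEYS
) -> RearrangementSet:
    """Merge records identical on ``keys``, summing duplicate_count.

    Controls for expression/amplification bias before any per-clone analysis:
    identical transcripts (same nucleotide sequence, isotype, subject and
    sorted subset by default) become one record whose duplicate_count is the
    sum; the first-seen sequence_id and row order are retained.  Total
    duplicate_count is conserved exactly.
    """
    df = rset.df
    if df.empty:
        return rset.with_df(df, "collapse: empty set")
    use_keys = [k for k in keys if k in df.columns]
    if not use_keys:
        raise ValidationError(f"no collapse keys present among {list(keys)}")
    codes = df.groupby(use_keys, sort=False, dropna=False).ngroup()
    keep = ~codes.duplicated()
    first = df.loc[keep].copy()
    sums = df["duplicate_count"].groupby(codes).sum()
    first["duplicate_count"] = sums.loc[codes[keep]].astype(int).to_numpy()
    return rset.with_df(
        first, f"collapse on {use_keys}: {len(df)} -> {len(first)} records"
    )


def filter_rearrangements(
    rset: RearrangementSet,
    v_gene_prefix: str | None = None,
    isotype: str | None = None,
    productive_only: bool = False,
) -> RearrangementSet:
    """Subset by V gene (allele-insensitive), isotype prefix, and productivity.

    ``v_gene_prefix`` matches at the gene level (``"IGHV4-34"`` matches
    ``IGHV4-34*01``; ``"IGHV4"`` matches the whole family).  ``isotype``
    matches the c_call prefix so ``"IGHG"`` covers IGHG1..4.
    """
    df = rset.df
    notes = []
    if v_gene_prefix:
        df = df[df["v_call"].map(lambda c: _gene_matches_prefix(c, v_gene_prefix))]
        notes.append(f"v_call~{v_gene_prefix}")
    if isotype:
        token = isotype.upper()
        if not any(token.startswith(k) for k in KNOWN_ISOTYPES):
            raise ValidationError(f"unknown isotype token: {isotype}")
        df = df[df["c_call"].str.upper().str.startswith(token)]
        notes.append(f"c_call~{isotype}")
    if productive_only:
        df = df[df["productive"].map(lambda v: bool(_parse_bool(v)))]
        notes.append("productive only")
    if not notes:
        return rset
    return rset.with_df(df, "filter: " + ", ".join(notes) + f" -> {len(df)} records")


def read_germline_reference(
    fasta_path: str | Path, bounds_path: str | Path
) -> dict[str, GermlineReference]:
    """Load germline V references from FASTA plus a JSON region-bounds sidecar.

    The sidecar maps allele name -> {region: [start, end]} with 1-based
    inclusive amino-acid coordinates; a ``"default"`` entry applies to alleles
    without their own entry.  Each reference is validated on load.
    """
    with open(bounds_path) as fh:
        bounds_raw = json.load(fh)
    default = bounds_raw.get("default")
    refs: dict[str, GermlineReference] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        name = record.id
        entry = bounds_raw.get(name, default)
        if entry is None:
            raise ValidationError(f"no region bounds for allele {name}")
        bounds = {k: (int(v[0]), int(v[1])) for k, v in entry.items()}
        ref = GermlineReference(name, str(record.seq).upper(), bounds)
        ref.validate()
        refs[name] = ref
    return refs


def write_germline_reference(
    refs: Iterable[GermlineReference], fasta_path: str | Path, bounds_path: str | Path
) -> None:
    refs = list(refs)
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.allele_name}\n{ref.sequence_nt}\n")
    with open(bounds_path, "w") as fh:
        json.dump(
            {r.allele_name: {k: list(v) for k, v in r.region_bounds.items()} for r in refs},
            fh,
            indent=1,
        )
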