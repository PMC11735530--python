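"""Germline alignment, somatic mutation calling, and VH4-34 hotspot classification.

The germline product of IGHV4-34 is intrinsically self-reactive: a hydrophobic
patch in framework region 1 (residues Q6, W7 plus A24, V25, Y26) forms the
epitope recognized by the 9G4 anti-idiotype antibody, and replacement mutations
there — or at the CDR2 N-glycosylation sequon N57-H58-S59, or at K90-L91-S92 in
FR3 — attenuate self-reactivity.  This module aligns each transcript to its
germline V gene, calls silent/replacement point mutations in germline
coordinates, and classifies each clone into one of seven categories
(GERMLINE, AVY, NHS, KLS, OTHER_REPLACEMENT, SILENT_ONLY, UNCLASSIFIABLE)
under a configurable precedence scheme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .airr_io import GermlineReference, RearrangementSet, gene_from_call, translate_nt
from .errors import ConfigurationError, MisassignmentError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class HotspotScheme:
    """Residue sets whose replacement mutations attenuate VH4-34 self-reactivity.

    Positions are 1-based amino-acid indices in the translated mature V region.
    ``hydrophobic_patch_aux`` (Q6, W7) contributes to the AVY trigger only when
    ``include_aux_in_avy`` is set; by default the trigger is the A24-V25-Y26
    core of the hydrophobic patch.
    """

    avy_positions: frozenset[int] = frozenset({24, 25, 26})
    hydrophobic_patch_aux: frozenset[int] = frozenset({6, 7})
    nhs_positions: frozenset[int] = frozenset({57, 58, 59})
    kls_positions: frozenset[int] = frozenset({90, 91, 92})
    include_aux_in_avy: bool = False

    def __post_init__(self) -> None:
        sets = [
            self.avy_positions,
            self.hydrophobic_patch_aux,
            self.nhs_positions,
            self.kls_positions,
        ]
        seen: set[int] = set()
        for s in sets:
            if seen & s:
                raise ConfigurationError("hotspot position sets must be disjoint")
            seen |= s

    @property
    def avy_trigger(self) -> frozenset[int]:
        if self.include_aux_in_avy:
            return self.avy_positions | self.hydrophobic_patch_aux
        return self.avy_positions

    def all_positions(self) -> frozenset[int]:
        return (
            self.avy_positions
            | self.hydrophobic_patch_aux
            | self.nhs_positions
            | self.kls_positions
        )

    def validate_against(self, germline: GermlineReference) -> None:
        n = len(germline.sequence_aa)
        bad = [p for p in self.all_positions() if p < 1 or p > n]
        if bad:
            raise ConfigurationError(
                f"hotspot positions {sorted(bad)} outside germline span 1..{n}"
            )


class CloneCategory(str, Enum):
    """Mutually exclusive per-clone mutation categories (precedence order)."""

    GERMLINE = "GERMLINE"
    AVY = "AVY"
    NHS = "NHS"
    KLS = "KLS"
    OTHER_REPLACEMENT = "OTHER_REPLACEMENT"
    SILENT_ONLY = "SILENT_ONLY"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


CATEGORY_ORDER = [c.value for c in CloneCategory]


@dataclass(frozen=True)
class Mutation:
    """A single nucleotide substitution in germline coordinates."""

    nt_position: int  # 1-based germline coordinate
    germline_nt: str
    observed_nt: str
    aa_position: int  # == ceil(nt_position / 3)
    germline_aa: str
    observed_aa: str
    region: str | None

    @property
    def is_silent(self) -> bool:
        return self.germline_aa == self.observed_aa

    def __post_init__(self) -> None:
        assert self.aa_position == math.ceil(self.nt_position / 3)


@dataclass
class MutationProfile:
    """All point mutations of one sequence relative to its germline V gene."""

    sequence_id: str
    mutations: list[Mutation] = field(default_factory=list)
    has_indel: bool = False
    n_ambiguous: int = 0  # mismatch columns skipped for N/ambiguity

    @property
    def n_silent(self) -> int:
        return sum(1 for m in self.mutations if m.is_silent)

    @property
    def n_replacement(self) -> int:
        return sum(1 for m in self.mutations if not m.is_silent)

    def replacement_positions(self) -> set[int]:
        return {m.aa_position for m in self.mutations if not m.is_silent}


@dataclass
class VAlignment:
    """Pairwise germline/observed alignment restricted to the V region.

    ``germline_aligned`` and ``observed_aligned`` are equal-length strings with
    ``-`` for gaps; ``observed_by_position[i]`` gives the observed base (or
    ``-`` for a deletion) at 1-based germline position ``i+1``.
    """

    sequence_id: str
    allele_name: str
    germline_aligned: str
    observed_aligned: str
    observed_by_position: list[str]
    identity: float
    has_indel: bool


def align_to_germline(
    rearrangement: pd.Series | dict,
    germline: GermlineReference,
    identity_floor: float = 0.70,
) -> VAlignment:
    """Globally align the V-region portion of a transcript to its germline.

    The read (V through J) is longer than the germline V gene, so the germline
    is aligned semi-globally: end gaps on the read are free, internal gaps are
    not.  Identity is computed over germline columns; below ``identity_floor``
    the assignment is considered wrong.

    Raises
    ------
    MisassignmentError
        if v_call does not match the germline gene, or identity < floor.
    """
    seq_id = str(rearrangement["sequence_id"])
    v_gene = gene_from_call(str(rearrangement["v_call"]))
    if v_gene != germline.gene:
        raise MisassignmentError(
            f"{seq_id}: v_call gene {v_gene} does not match germline {germline.gene}"
        )
    observed = str(rearrangement["sequence"]).upper()
    if not observed:
        raise MisassignmentError(f"{seq_id}: empty sequence")

    result = edlib.align(germline.sequence_nt, observed, mode="HW", task="path")
    nice = edlib.getNiceAlignment(result, germline.sequence_nt, observed)
    g_row = nice["query_aligned"]
    o_row = nice["target_aligned"]

    # At the V/junction boundary a terminal mismatch and a terminal deletion
    # have equal edit cost and edlib may report the gap; prefer the
    # substitution reading by consuming the next read bases, which exist
    # whenever the read extends past the V region.
    k = 0
    while k < len(o_row) and o_row[-1 - k] == "-" and g_row[-1 - k] != "-":
        k += 1
    if k:
        end = result["locations"][0][1]  # inclusive end in the read
        tail = observed[end + 1 : end + 1 + k]
        if len(tail) == k:
            o_row = o_row[: len(o_row) - k] + tail

    observed_by_position: list[str] = []
    matches = 0
    has_indel = False
    for g, o in zip(g_row, o_row):
        if g == "-":
            has_indel = True  # insertion relative to germline
            continue
        observed_by_position.append(o)
        if o == "-":
            has_indel = True
        elif o == g:
            matches += 1
    identity = matches / max(len(germline.sequence_nt), 1)
    if identity < identity_floor:
        raise MisassignmentError(
            f"{seq_id}: identity {identity:.2f} to {germline.allele_name} below "
            f"floor {identity_floor:.2f}"
        )
    return VAlignment(
        sequence_id=seq_id,
        allele_name=germline.allele_name,
        germline_aligned=g_row,
        observed_aligned=o_row,
        observed_by_position=observed_by_position,
        identity=identity,
        has_indel=has_indel,
    )


def call_mutations(alignment: VAlignment, germline: GermlineReference) -> MutationProfile:
    """Call per-site mutations from a V alignment, codon-aware.

    Silent vs. replacement is decided by translating the full observed codon
    (all three positions), so two hits in one codon are judged jointly.
    Codons disrupted by a gap yield no per-site calls; mismatch columns with an
    ambiguous observed base (N) are skipped and tallied in ``n_ambiguous``.
    """
    profile = MutationProfile(alignment.sequence_id, has_indel=alignment.has_indel)
    g_nt = germline.sequence_nt
    obs = alignment.observed_by_position
    n_codons = len(g_nt) // 3
    for codon_idx in range(n_codons):
        start = codon_idx * 3
        g_codon = g_nt[start : start + 3]
        o_codon = obs[start : start + 3]
        if "-" in o_codon:
            continue  # gap-disrupted codon: no per-site calls
        mismatches = [k for k in range(3) if o_codon[k] != g_codon[k]]
        if not mismatches:
            continue
        ambiguous = [k for k in mismatches if o_codon[k] not in _BASES]
        if ambiguous:
            profile.n_ambiguous += len(ambiguous)
            mismatches = [k for k in mismatches if k not in ambiguous]
        if not mismatches:
            continue
        # translate the observed codon using germline bases at ambiguous sites
        codon_for_translation = "".join(
            o_codon[k] if o_codon[k] in _BASES else g_codon[k] for k in range(3)
        )
        aa_position = codon_idx + 1
        germline_aa = translate_nt(g_codon)
        observed_aa = translate_nt(codon_for_translation)
        region = germline.region_of(aa_position)
        for k in mismatches:
            profile.mutations.append(
                Mutation(
                    nt_position=start + k + 1,
                    germline_nt=g_codon[k],
                    observed_nt=o_codon[k],
                    aa_position=aa_position,
                    germline_aa=germline_aa,
                    observed_aa=observed_aa,
                    region=region,
                )
            )
    return profile


def classify_idiotope(
    profile: MutationProfile, scheme: HotspotScheme = HotspotScheme()
) -> CloneCategory:
    """Assign one of seven mutation categories under hotspot precedence.

    Precedence: AVY > NHS > KLS > OTHER_REPLACEMENT > SILENT_ONLY > GERMLINE;
    any indel makes the clone UNCLASSIFIABLE.  A replacement at an AVY-trigger
    position dominates regardless of other mutations, mirroring its outsized
    effect on 9G4 idiotope loss.
    """
    if profile.has_indel:
        return CloneCategory.UNCLASSIFIABLE
    repl = profile.replacement_positions()
    if repl & scheme.avy_trigger:
        return CloneCategory.AVY
    if repl & scheme.nhs_positions:
        return CloneCategory.NHS
    if repl & scheme.kls_positions:
        return CloneCategory.KLS
    if profile.n_replacement > 0:
        return CloneCategory.OTHER_REPLACEMENT
    if profile.n_silent > 0:
        return CloneCategory.SILENT_ONLY
    return CloneCategory.GERMLINE


def hotspot_flags(profile: MutationProfile, scheme: HotspotScheme = HotspotScheme()) -> dict:
    """Non-exclusive per-hotspot flags, so any precedence can be re-derived."""
    repl = profile.replacement_positions()
    return {
        "hits_avy": bool(repl & scheme.avy_positions),
        "hits_aux": bool(repl & scheme.hydrophobic_patch_aux),
        "hits_nhs": bool(repl & scheme.nhs_positions),
        "hits_kls": bool(repl & scheme.kls_positions),
    }


def profile_set(
    rset: RearrangementSet,
    germlines: dict[str, GermlineReference] | GermlineReference,
    scheme: HotspotScheme = HotspotScheme(),
    identity_floor: float = 0.70,
) -> pd.DataFrame:
    """Align, call and classify every record of a set against its germline.

    ``germlines`` maps gene names to references (or a single reference used for
    all records).  Returns the set's DataFrame with extension columns
    ``idiotope_category``, ``n_replacement``, ``n_silent``, ``has_indel`` plus
    the non-exclusive hotspot flags.  Records whose gene has no reference or
    that fail the identity floor get UNCLASSIFIABLE.
    """
    if isinstance(germlines, GermlineReference):
        germlines = {germlines.gene: germlines}
    for ref in germlines.values():
        scheme.validate_against(ref)
    rows = []
    for _, rec in rset.df.iterrows():
        gene = gene_from_call(str(rec["v_call"]))
        ref = germlines.get(gene)
        out = {
            "sequence_id": rec["sequence_id"],
            "idiotope_category": CloneCategory.UNCLASSIFIABLE.value,
            "n_replacement": 0,
            "n_silent": 0,
            "has_indel": False,
            "hits_avy": False,
            "hits_aux": False,
            "hits_nhs": False,
            "hits_kls": False,
        }
        if ref is not None:
            try:
                aln = align_to_germline(rec, ref, identity_floor=identity_floor)
            except MisassignmentError as exc:
                logger.warning("profiling skipped: %s", exc)
            else:
                profile = call_mutations(aln, ref)
                out.update(
                    idiotope_category=classify_idiotope(profile, scheme).value,
                    n_replacement=profile.n_replacement,
                    n_silent=profile.n_silent,
                    has_indel=profile.has_indel,
                    **hotspot_flags(profile, scheme),
                )
        rows.append(out)
    calls = pd.DataFrame(rows)
    merged = rset.df.drop(columns=[c for c in calls.columns if c != "sequence_id" and c in rset.df.columns])
    return merged.merge(calls, on="sequence_id", how="left")


def summarize_categories(
    labeled: Iterable[tuple[str, CloneCategory | str]] | pd.DataFrame,
    group_col: str = "subject_id",
    category_col: str = "idiotope_category",
) -> pd.DataFrame:
    """Per-group category counts and fractions (the mutation-category table).

    Accepts either an iterable of (group label, category) pairs or a DataFrame
    with ``group_col``/``category_col``.  Rows are ordered by group then by
    category precedence; per group, fractions sum to 1.  Empty groups are
    omitted with a logged warning.
    """
    if isinstance(labeled, pd.DataFrame):
        pairs = list(zip(labeled[group_col].astype(str), labeled[category_col]))
    else:
        pairs = list(labeled)
    rows = []
    by_group: dict[str, list[str]] = {}
    for group, cat in pairs:
        value = cat.value if isinstance(cat, CloneCategory) else str(cat)
        by_group.setdefault(str(group), []).append(value)
    for group in sorted(by_group):
        cats = by_group[group]
        n_total = len(cats)
        if n_total == 0:
            logger.warning("group %s is empty; omitted from category table", group)
            continue
        counts = pd.Series(cats).value_counts()
        for cat in CATEGORY_ORDER:
            count = int(counts.get(cat, 0))
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "count": count,
                    "fraction": count / n_total,
                    "n_total": n_total,
                }
            )
    return pd.DataFrame(rows, columns=["group", "category", "count", "fraction", "n_total"])
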