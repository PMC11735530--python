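"""Synthetic AIRR repertoires with per-sequence ground truth.

Generates heavy-chain rearrangement sets that emulate the repertoire structure
seen in hypomorphic RAG deficiency versus healthy donors: a polyclonal
background with power-law clone sizes, a configurable IGHV4-34 fraction
(healthy-like ~5-10% of clones versus an expanded ~50%), depletion of the
distal JH5/JH6 segments, controllable somatic-hypermutation category mixes at
the VH4-34 hotspot triplets, isotype assignment and non-productive
rearrangements.  Every emitted sequence carries a truth record (clone, category,
isotype, productivity), which makes each pipeline stage testable by parameter
recovery without any external data.

The germline references used here are SYNTHETIC: a 98-residue IGHV4-34-like V
region built so that the hotspot residues sit exactly at the canonical linear
positions (Q6 W7, A24 V25 Y26 in FR1; N57 H58 S59 in CDR2; K90 L91 S92 in FR3),
plus derived variants for the other gene names.  They are stand-ins for a real
IMGT germline database, adequate for exercising alignment, mutation calling and
classification logic, not for annotating real reads.

Junctions are random in-frame nucleotide stretches flanked by the conserved
Cys/Trp anchor codons — no TdT/exonuclease junction model is attempted.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .airr_io import GermlineReference, RearrangementSet, translate_nt
from .errors import ConfigurationError, GenerationError
from .mutation_profiling import CloneCategory, HotspotScheme

# --- synthetic germline construction ---------------------------------------

#: 98-aa IGHV4-34-like V region (synthetic); hotspot residues at their
#: canonical positions: Q6 W7 / A24 V25 Y26 / N57 H58 S59 / K90 L91 S92.
BASE_V_AA = (
    "QVQLQQWGAG"  # 1-10
    "LLKPSETLSL"  # 11-20
    "TCGAVYGGSF"  # 21-30
    "SGYYWSWIRQ"  # 31-40
    "PPGKGLEWIG"  # 41-50
    "EIYQSGNHST"  # 51-60
    "NYNPSLKSRV"  # 61-70
    "TISVDTSKNQ"  # 71-80
    "FSLKLSSVTK"  # 81-90
    "LSDTAVYY"    # 91-98
)

#: 1-based inclusive amino-acid intervals of the framework/CDR regions.
BASE_REGION_BOUNDS: dict[str, tuple[int, int]] = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 98),
}

_PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    {a + b + c for a in _BASES for b in _BASES for c in _BASES} - _STOP_CODONS
)

OTHER_V_GENES = (
    "IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV3-30", "IGHV4-39", "IGHV5-51", "IGHV6-1",
)
_OTHER_V_WEIGHTS = (0.18, 0.12, 0.25, 0.15, 0.10, 0.12, 0.08)

J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")

#: Baseline J-segment usage; distal JH5+JH6 carry 0.30 of the mass.
BASELINE_J_USAGE: dict[str, float] = {
    "IGHJ1": 0.03, "IGHJ2": 0.07, "IGHJ3": 0.10,
    "IGHJ4": 0.50, "IGHJ5": 0.10, "IGHJ6": 0.20,
}


def reverse_translate(aa: str) -> str:
    """Deterministic reverse translation using one fixed codon per residue."""
    return "".join(_PREFERRED_CODON[r] for r in aa)


def germline_reference(gene: str = "IGHV4-34", scheme: HotspotScheme | None = None) -> GermlineReference:
    """Synthetic germline V reference for ``gene``.

    ``IGHV4-34`` is the base sequence; other gene names get deterministic
    residue substitutions at non-hotspot positions (seeded from the gene name)
    so that different genes have distinct but alignable sequences.
    """
    scheme = scheme or HotspotScheme()
    aa = BASE_V_AA
    if gene != "IGHV4-34":
        rng = np.random.default_rng(zlib.crc32(gene.encode()))
        protected = scheme.all_positions()
        candidates = [p for p in range(1, len(aa) + 1) if p not in protected]
        positions = rng.choice(candidates, size=14, replace=False)
        chars = list(aa)
        for pos in sorted(int(p) for p in positions):
            current = chars[pos - 1]
            options = [r for r in _AA_ALPHABET if r != current]
            chars[pos - 1] = options[int(rng.integers(len(options)))]
        aa = "".join(chars)
    return GermlineReference(f"{gene}*01", reverse_translate(aa), dict(BASE_REGION_BOUNDS))


def synthetic_germlines(genes) -> dict[str, GermlineReference]:
    return {g: germline_reference(g) for g in genes}


def _j_segment(gene: str) -> str:
    """Deterministic 33-nt synthetic J segment (in frame, stop-free)."""
    rng = np.random.default_rng(zlib.crc32(gene.encode()) ^ 0x5A5A)
    return "".join(_NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))] for _ in range(11))


J_SEGMENTS: dict[str, str] = {g: _j_segment(g) for g in J_GENES}


# --- configuration ----------------------------------------------------------

def _default_junction_length_law() -> dict[int, float]:
    # triangular distribution over CDR3-containing junction lengths 10..20 aa,
    # peaked at 15 — a realistic heavy-chain junction length range
    lengths = np.arange(10, 21)
    weights = 6.0 - np.abs(lengths - 15)
    weights = weights / weights.sum()
    return {int(l): float(w) for l, w in zip(lengths, weights)}


def _default_isotype_probs() -> dict[str, float]:
    return {"IGHM": 0.70, "IGHD": 0.15, "IGHG": 0.10, "IGHA": 0.05}


@dataclass
class SimulationConfig:
    """All knobs of the repertoire generator (see module docstring).

    ``v_usage``/``j_usage`` are per-clone gene probabilities; when ``v_usage``
    is None it is built from ``ighv4_34_fraction`` with the remaining mass
    spread over a fixed panel of other V genes.  ``distal_j_depletion``
    multiplies the distal (JH5/JH6) mass by the given factor and redistributes
    the removed mass over the non-distal genes, so a baseline distal mass m
    becomes exactly m x factor.  When ``category_mix`` is given, each clone's
    V-region mutations are implanted explicitly to realize the requested
    category and background SHM in the V region is disabled (the truth label
    is then exact); otherwise ``shm_rate`` drives a site-independent
    substitution process.
    """

    n_sequences: int = 1000
    ighv4_34_fraction: float = 0.07
    v_usage: dict[str, float] | None = None
    j_usage: dict[str, float] = field(default_factory=lambda: dict(BASELINE_J_USAGE))
    distal_j_depletion: float = 1.0
    distal_genes: tuple[str, ...] = ("IGHJ5", "IGHJ6")
    clone_size_law: str = "zipf"  # "zipf" | "negative_binomial"
    zipf_alpha: float = 1.5
    nb_r: float = 1.0
    nb_p: float = 0.5
    shm_rate: float = 0.0
    hotspot_multipliers: dict[str, float] = field(default_factory=dict)
    category_mix: dict[str, float] | None = None
    isotype_probs: dict[str, float] = field(default_factory=_default_isotype_probs)
    nonproductive_fraction: float = 0.0
    junction_length_law: dict[int, float] = field(default_factory=_default_junction_length_law)
    subject_id: str = "SIM"
    subset_label: str = "CD27+IgM+"
    seed: int = 0

    def resolved_v_usage(self) -> dict[str, float]:
        if self.v_usage is not None:
            return dict(self.v_usage)
        f = self.ighv4_34_fraction
        rest = 1.0 - f
        total = sum(_OTHER_V_WEIGHTS)
        usage = {"IGHV4-34": f}
        usage.update(
            {g: rest * w / total for g, w in zip(OTHER_V_GENES, _OTHER_V_WEIGHTS)}
        )
        return usage

    def resolved_j_usage(self) -> dict[str, float]:
        usage = dict(self.j_usage)
        factor = self.distal_j_depletion
        if factor == 1.0:
            return usage
        distal = [g for g in usage if g in self.distal_genes]
        proximal = [g for g in usage if g not in self.distal_genes]
        removed = sum(usage[g] * (1.0 - factor) for g in distal)
        for g in distal:
            usage[g] *= factor
        proximal_mass = sum(usage[g] for g in proximal)
        for g in proximal:
            usage[g] += removed * usage[g] / proximal_mass
        return usage

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        if self.distal_j_depletion < 0:
            raise ConfigurationError("distal_j_depletion must be >= 0")
        if not 0 <= self.shm_rate < 1:
            raise ConfigurationError("shm_rate must be in [0, 1)")
        if not 0 <= self.nonproductive_fraction <= 1:
            raise ConfigurationError("nonproductive_fraction must be in [0, 1]")
        for name, probs in (
            ("v_usage", self.resolved_v_usage()),
            ("j_usage", self.resolved_j_usage()),
            ("isotype_probs", self.isotype_probs),
            ("junction_length_law", self.junction_length_law),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} contains a negative probability")
        if self.category_mix is not None:
            total = sum(self.category_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"category_mix sums to {total}, not 1")
            valid = {c.value for c in CloneCategory}
            bad = set(self.category_mix) - valid
            if bad:
                raise ConfigurationError(f"unknown categories in mix: {sorted(bad)}")
        if self.clone_size_law not in ("zipf", "negative_binomial"):
            raise ConfigurationError(f"unknown clone_size_law: {self.clone_size_law}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-sequence truth labels: the oracle for every recovery test."""

    df: pd.DataFrame  # sequence_id, clone_id, v_gene, j_gene, category, isotype, productive, n_implanted

    def category_fractions(self, productive_only: bool = True) -> pd.Series:
        df = self.df
        if productive_only:
            df = df[df["productive"]]
        labeled = df[df["category"] != ""]
        return labeled["category"].value_counts(normalize=True).sort_index()


# --- mutation processes -----------------------------------------------------

def _single_nt_variants(codon: str):
    for k in range(3):
        for base in _BASES:
            if base != codon[k]:
                yield k, base, codon[:k] + base + codon[k + 1 :]


def _codon(seq: str, aa_position: int) -> str:
    return seq[(aa_position - 1) * 3 : aa_position * 3]


def inject_hotspot_mutations(
    sequence_nt: str,
    category: CloneCategory | str,
    scheme: HotspotScheme = HotspotScheme(),
    rng: np.random.Generator | int = 0,
) -> tuple[str, list[tuple[int, str, str, int]]]:
    """Implant the minimal edit that realizes ``category`` under the classifier.

    One single-nucleotide edit is placed: a non-synonymous change at a
    position drawn from the category's hotspot set (AVY/NHS/KLS), a
    non-synonymous change outside every hotspot set (OTHER_REPLACEMENT), or a
    synonymous change outside every hotspot set (SILENT_ONLY).  GERMLINE is a
    no-op.  Returns the mutated sequence and the edit list as
    (nt_position, germline_base, new_base, aa_position) tuples.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    category = CloneCategory(category)
    if category == CloneCategory.GERMLINE:
        return sequence_nt, []
    n_aa = len(sequence_nt) // 3
    hotspots = scheme.all_positions()

    if category in (CloneCategory.AVY, CloneCategory.NHS, CloneCategory.KLS):
        pool = {
            CloneCategory.AVY: scheme.avy_trigger,
            CloneCategory.NHS: scheme.nhs_positions,
            CloneCategory.KLS: scheme.kls_positions,
        }[category]
        synonymous = False
    elif category == CloneCategory.OTHER_REPLACEMENT:
        pool = set(range(1, n_aa + 1)) - hotspots
        synonymous = False
    elif category == CloneCategory.SILENT_ONLY:
        pool = set(range(1, n_aa + 1)) - hotspots
        synonymous = True
    else:
        raise GenerationError(f"cannot inject mutations for category {category}")

    positions = [p for p in sorted(pool) if p <= n_aa]
    rng.shuffle(positions)
    for aa_position in positions:
        codon = _codon(sequence_nt, aa_position)
        aa = translate_nt(codon)
        options = [
            (k, base, variant)
            for k, base, variant in _single_nt_variants(codon)
            if variant not in _STOP_CODONS
            and (translate_nt(variant) == aa) == synonymous
        ]
        if not options:
            continue
        k, base, variant = options[int(rng.integers(len(options)))]
        nt_position = (aa_position - 1) * 3 + k + 1
        mutated = (
            sequence_nt[: nt_position - 1] + base + sequence_nt[nt_position:]
        )
        return mutated, [(nt_position, codon[k], base, aa_position)]
    raise GenerationError(
        f"no eligible single-nucleotide edit for category {category.value}"
    )


def apply_shm(
    sequence_nt: str,
    rate: float,
    multipliers: Mapping[str, float] | None = None,
    rng: np.random.Generator | int = 0,
    scheme: HotspotScheme = HotspotScheme(),
) -> tuple[str, list[tuple[int, str, str, int]]]:
    """Site-independent SHM: substitute each site with probability rate x multiplier.

    ``multipliers`` maps hotspot-set names (``avy``, ``aux``, ``nhs``, ``kls``)
    to relative rates applied to every nucleotide of the covered codons; other
    sites use the base rate.  The substituted base is uniform over the three
    alternatives.  Returns the mutated sequence and the full edit list.
    """
    if not 0 <= rate <= 1:
        raise ConfigurationError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(sequence_nt)
    site_rates = np.full(n, rate)
    if multipliers:
        sets = {
            "avy": scheme.avy_positions,
            "aux": scheme.hydrophobic_patch_aux,
            "nhs": scheme.nhs_positions,
            "kls": scheme.kls_positions,
        }
        for name, factor in multipliers.items():
            if name not in sets:
                raise ConfigurationError(f"unknown hotspot-set name: {name}")
            for aa_position in sets[name]:
                lo = (aa_position - 1) * 3
                site_rates[lo : lo + 3] = rate * factor
    hits = np.nonzero(rng.random(n) < site_rates)[0]
    if hits.size == 0:
        return sequence_nt, []
    chars = list(sequence_nt)
    edits = []
    for i in hits:
        old = chars[i]
        alternatives = [b for b in _BASES if b != old]
        new = alternatives[int(rng.integers(3))]
        chars[i] = new
        edits.append((int(i) + 1, old, new, int(i) // 3 + 1))
    return "".join(chars), edits


# --- repertoire generation --------------------------------------------------

def _draw_clone_size(config: SimulationConfig, rng: np.random.Generator, remaining: int) -> int:
    if config.clone_size_law == "zipf":
        size = int(rng.zipf(config.zipf_alpha))
    else:
        size = 1 + int(rng.negative_binomial(config.nb_r, config.nb_p))
    return min(size, remaining)


def _random_junction(rng: np.random.Generator, aa_length: int) -> str:
    """In-frame junction: Cys anchor + random stop-free codons + Trp anchor."""
    middle = "".join(
        _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
        for _ in range(aa_length - 2)
    )
    return "TGT" + middle + "TGG"


def _choice(rng: np.random.Generator, probs: Mapping[str, float] | Mapping[int, float]):
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def simulate_repertoire(
    config: SimulationConfig,
    germlines: dict[str, GermlineReference] | None = None,
    scheme: HotspotScheme = HotspotScheme(),
) -> tuple[RearrangementSet, GroundTruth]:
    """Generate an AIRR rearrangement set plus per-sequence ground truth.

    Clones are drawn until ``n_sequences`` members exist: each clone gets a V
    gene, a J gene, an in-frame junction of drawn length and (optionally) an
    implanted mutation category; members share the clone's mutated V region
    and junction, and individually receive an isotype and a productivity flag.
    Non-productive members get a frameshifted (1-nt-truncated) junction.  The
    same seed gives byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    v_usage = config.resolved_v_usage()
    j_usage = config.resolved_j_usage()
    if germlines is None:
        germlines = synthetic_germlines(v_usage)
    missing = set(v_usage) - set(germlines)
    if missing:
        raise ConfigurationError(f"no germline reference for: {sorted(missing)}")
    for gene in j_usage:
        if gene not in J_SEGMENTS:
            raise ConfigurationError(f"no J segment for: {gene}")

    records = []
    truth_rows = []
    seq_no = 0
    clone_no = 0
    remaining = config.n_sequences
    while remaining > 0:
        size = _draw_clone_size(config, rng, remaining)
        remaining -= size
        clone_no += 1
        clone_id = f"tc{clone_no:06d}"
        v_gene = _choice(rng, v_usage)
        j_gene = _choice(rng, j_usage)
        junction = _random_junction(rng, int(_choice(rng, config.junction_length_law)))
        germline_nt = germlines[v_gene].sequence_nt
        category = None
        implanted: list = []
        if config.category_mix is not None:
            category = CloneCategory(_choice(rng, config.category_mix))
            v_nt, implanted = inject_hotspot_mutations(germline_nt, category, scheme, rng)
        else:
            v_nt = germline_nt

        for _ in range(size):
            seq_no += 1
            sid = f"S{seq_no:07d}"
            member_v = v_nt
            member_edits = list(implanted)
            if config.category_mix is None and config.shm_rate > 0:
                member_v, member_edits = apply_shm(
                    member_v, config.shm_rate, config.hotspot_multipliers, rng, scheme
                )
            productive = rng.random() >= config.nonproductive_fraction
            member_junction = junction if productive else junction[:-1]
            junction_aa = translate_nt(member_junction) if productive else ""
            isotype = _choice(rng, config.isotype_probs)
            sequence = member_v + member_junction + J_SEGMENTS[j_gene]
            records.append(
                {
                    "sequence_id": sid,
                    "sequence": sequence,
                    "locus": "IGH",
                    "v_call": f"{v_gene}*01",
                    "j_call": f"{j_gene}*01",
                    "c_call": isotype,
                    "junction": member_junction,
                    "junction_aa": junction_aa,
                    "productive": productive,
                    "duplicate_count": 1,
                    "subject_id": config.subject_id,
                    "subset_label": config.subset_label,
                }
            )
            truth_rows.append(
                {
                    "sequence_id": sid,
                    "clone_id": clone_id,
                    "v_gene": v_gene,
                    "j_gene": j_gene,
                    "category": category.value if category is not None else "",
                    "isotype": isotype,
                    "productive": productive,
                    "n_implanted": len(member_edits),
                }
            )

    rset = RearrangementSet(
        pd.DataFrame(records),
        [
            f"simulated {config.n_sequences} sequences in {clone_no} clones "
            f"(seed={config.seed})"
        ],
    )
    return rset, GroundTruth(pd.DataFrame(truth_rows))


# --- presets ----------------------------------------------------------------

#: Healthy-donor-like mutation-category mix: ~25% unmutated receptors and an
#: AVY+NHS mass in the reported 30-50% band.
HD_CATEGORY_MIX = {
    "GERMLINE": 0.25, "AVY": 0.32, "NHS": 0.18,
    "KLS": 0.10, "SILENT_ONLY": 0.09, "OTHER_REPLACEMENT": 0.06,
}

#: Affected-sibling-like mix: AVY (hydrophobic-patch) mutations rare, isolated
#: KLS / scattered "other" / silent mutations elevated, unmutated mass kept.
IIE_CATEGORY_MIX = {
    "GERMLINE": 0.25, "AVY": 0.02, "NHS": 0.08,
    "KLS": 0.25, "SILENT_ONLY": 0.22, "OTHER_REPLACEMENT": 0.18,
}


def hd_like_config(seed: int = 0, n_sequences: int = 10_000) -> SimulationConfig:
    """Healthy-donor-like repertoire: polyclonal, ~7% IGHV4-34, no distal loss."""
    return SimulationConfig(
        n_sequences=n_sequences,
        ighv4_34_fraction=0.07,
        distal_j_depletion=1.0,
        clone_size_law="zipf",
        zipf_alpha=3.0,
        category_mix=dict(HD_CATEGORY_MIX),
        nonproductive_fraction=0.10,
        subject_id="HD-like",
        seed=seed,
    )


def iie_like_config(seed: int = 0, n_sequences: int = 10_000) -> SimulationConfig:
    """Affected-sibling-like repertoire: oligoclonal, IGHV4-34-expanded (~50%),
    distal JH5/JH6 halved, hydrophobic-patch (AVY) mutations rare."""
    return SimulationConfig(
        n_sequences=n_sequences,
        ighv4_34_fraction=0.50,
        distal_j_depletion=0.5,
        clone_size_law="zipf",
        zipf_alpha=1.5,
        category_mix=dict(IIE_CATEGORY_MIX),
        nonproductive_fraction=0.10,
        subject_id="IIe-like",
        seed=seed,
    )


PRESETS = {"hd": hd_like_config, "iie": iie_like_config}
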