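"""Synthetic SILAC, spectral-count and exon/cluster data with known truth.

Every downstream stage of the pipeline is exercised against data whose
ground truth is planted here: per-protein abundance ratios across the
three complex states, a global mixing error carried by the anchor
proteins, and exon loci whose CLIP clusters sit in known positional
zones with a branch-point consensus planted in the upstream intron.

The SILAC generator mimics the measurement model of a two-channel
experiment: each peptide of a protein is observed as a light and a heavy
intensity whose expected ratio is (true fold change x mixing error),
with independent multiplicative log-normal noise on each channel.
Anchor proteins (the cap-binding proteins CBP20/CBP80 by default) have
true fold change exactly 1 in every state pair, so their observed ratio
isolates the mixing error — exactly the property anchor normalization
relies on.

All generators are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clip import ClipCluster, ExonModel
from .errors import ConfigError, GenerationError

_SQRT2 = math.sqrt(2.0)

COMPLEX_PAIRS = ("active_vs_repressed", "edc_vs_repressed")

_AA = np.array(list("ACDEFGHILMNPQSTVWY"))

# Default binding-architecture composition of a repressed-exon cohort:
# 95 exons of which 56 (40 bound in both flanking introns, plus 8 + 8
# bound on one side) carry regulator clusters only in distal intronic
# zones; the rest also touch the branch-point/3'ss region or the exon,
# always together with at least one distal cluster (cohorts of repressed
# exons do not show exon-only or 3'ss-only binding).
DEFAULT_ZONE_COUNTS = {
    "a_d": 40, "a_only": 8, "d_only": 8,
    "b_distal": 19, "c_distal": 10, "b_c_distal": 10,
}

#: clusters planted per architecture (zone labels in classification vocabulary)
ARCHITECTURE_ZONES = {
    "a_only": ("a",),
    "d_only": ("d",),
    "a_d": ("a", "d"),
    "b_distal": ("b", "d"),
    "c_distal": ("c", "a"),
    "b_c_distal": ("b", "c", "d"),
}

#: architecture class the classifier should report for each planted architecture
ARCHITECTURE_CLASS = {
    "a_only": "distal-only",
    "d_only": "distal-only",
    "a_d": "distal-only",
    "b_distal": "contains-b",
    "c_distal": "contains-c",
    "b_c_distal": "mixed",
}

BPS_MOTIF = "CTCAG"  # canonical branch point pentamer, branch A at index 3


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    fold_changes: dict | None = None          # protein -> {pair -> true ratio}
    mixing_error: float | None = None
    zone_labels: dict | None = None           # cluster_id -> zone
    architectures: dict | None = None         # exon_id -> architecture class
    bps_offsets: dict | None = None           # exon_id -> planted branch-A offset
    delta_psi: dict | None = None             # exon_id -> planted delta-PSI


# ---------------------------------------------------------------------------
# SILAC peptide tables


@dataclass
class SilacSimConfig:
    """Parameters of a simulated two-channel comparison experiment.

    ``fold_changes`` maps protein -> {complex_pair -> true light/heavy
    abundance ratio} (a bare number applies to every pair).  Proteins not
    listed, and the anchors always, have true ratio 1.  ``mixing_error``
    multiplies the light channel of every peptide, emulating unequal
    molar mixing of the two complexes.  ``log2_noise_sd`` is the standard
    deviation, in log2 units, of the multiplicative noise on a peptide's
    light/heavy RATIO; it is realized as independent noise of
    ``log2_noise_sd / sqrt(2)`` on each channel, so per-channel
    intensities fluctuate too but their ratio carries exactly the stated
    scatter.  A peptide is absent from one (randomly chosen) channel
    with probability ``missing_rate``.
    """

    n_proteins: int = 20
    peptides_per_protein: tuple[int, int] = (3, 8)
    log2_noise_sd: float = 0.2
    anchor_ids: tuple[str, ...] = ("CBP20", "CBP80")
    mixing_error: float = 1.0
    fold_changes: dict = field(default_factory=dict)
    base_intensity: float = 1e6
    missing_rate: float = 0.0
    seed: int = 0
    complex_pairs: tuple[str, ...] = COMPLEX_PAIRS

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein must satisfy 1 <= min <= max")
        if self.log2_noise_sd < 0:
            raise ConfigError("log2_noise_sd must be >= 0")
        if self.mixing_error <= 0:
            raise ConfigError("mixing_error must be > 0")
        if self.base_intensity <= 0:
            raise ConfigError("base_intensity must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        self.fold_changes = {
            p: (dict(v) if isinstance(v, dict)
                else {pair: float(v) for pair in self.complex_pairs})
            for p, v in self.fold_changes.items()
        }
        for p, per_pair in self.fold_changes.items():
            for pair, fc in per_pair.items():
                if fc <= 0:
                    raise ConfigError(f"fold_changes[{p}][{pair}] must be > 0")
                if p in self.anchor_ids and fc != 1.0:
                    raise ConfigError(
                        f"fold_changes[{p}]: anchors are equimolar by definition "
                        "(true ratio must be 1)")


def _protein_names(config: SilacSimConfig) -> list[str]:
    names = list(config.anchor_ids)
    names += [p for p in config.fold_changes if p not in names]
    i = 1
    while len(names) < config.n_proteins:
        cand = f"P{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    if len(names) > config.n_proteins:
        raise ConfigError(
            "n_proteins smaller than the number of named proteins "
            f"({len(names)} named, n_proteins={config.n_proteins})")
    return names


def _peptide_seq(rng: np.random.Generator) -> str:
    n = int(rng.integers(7, 14))
    body = "".join(rng.choice(_AA, size=n))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_silac_experiment(config: SilacSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a peptide-level quantification table for every complex pair.

    Returns the peptide table (columns ``peptide, protein, complex_pair,
    intensity_light, intensity_heavy``; absent channels NaN) and the
    recorded truth.  For every protein the expected light/heavy ratio is
    true fold change x mixing_error; anchors sit at mixing_error.
    """
    rng = np.random.default_rng(config.seed)
    proteins = _protein_names(config)
    lo, hi = config.peptides_per_protein

    truth_fc = {
        p: {pair: float(config.fold_changes.get(p, {}).get(pair, 1.0))
            for pair in config.complex_pairs}
        for p in proteins
    }
    for a in config.anchor_ids:
        if a in truth_fc:
            truth_fc[a] = {pair: 1.0 for pair in config.complex_pairs}

    rows = []
    for pair in config.complex_pairs:
        for protein in proteins:
            n_pep = int(rng.integers(lo, hi + 1))
            fc = truth_fc[protein][pair]
            for _ in range(n_pep):
                base = config.base_intensity * 10.0 ** rng.uniform(-1.5, 1.5)
                eps_l, eps_h = rng.normal(0.0, config.log2_noise_sd / _SQRT2, size=2)
                light = base * fc * config.mixing_error * 2.0 ** eps_l
                heavy = base * 2.0 ** eps_h
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    if rng.random() < 0.5:
                        light = np.nan
                    else:
                        heavy = np.nan
                rows.append((_peptide_seq(rng), protein, pair, light, heavy))

    table = pd.DataFrame(rows, columns=["peptide", "protein", "complex_pair",
                                        "intensity_light", "intensity_heavy"])
    return table, SimTruth(fold_changes=truth_fc, mixing_error=config.mixing_error)


def generate_reference_spike_intensities(
    config: SilacSimConfig,
    states: tuple[str, ...] = ("repressed", "active", "edc"),
    state_abundances: dict | None = None,
    loading: dict | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the spiked-reference design: three light complexes, one heavy mix.

    ``state_abundances`` maps protein -> {state -> true abundance};
    when omitted it is derived from ``config.fold_changes`` by treating
    the repressed state as 1, ``active_vs_repressed`` as the active
    abundance and ``edc_vs_repressed`` as the EDC abundance.  ``loading``
    optionally inflates all light intensities of a state (per-state
    mixing error); anchors carry it too, so normalization removes it.
    """
    rng = np.random.default_rng(config.seed + 1)
    proteins = _protein_names(config)
    loading = loading or {}
    if state_abundances is None:
        state_abundances = {}
        for p in proteins:
            per_pair = config.fold_changes.get(p, {})
            if isinstance(per_pair, dict):
                act = float(per_pair.get("active_vs_repressed", 1.0))
                edc = float(per_pair.get("edc_vs_repressed", 1.0))
            else:
                act = edc = float(per_pair)
            if p in config.anchor_ids:
                act = edc = 1.0
            state_abundances[p] = {"repressed": 1.0, "active": act, "edc": edc}

    rows = []
    for state in states:
        infl = float(loading.get(state, 1.0))
        for protein in proteins:
            base = config.base_intensity * 10.0 ** rng.uniform(-1.0, 1.0)
            eps_l, eps_h = rng.normal(0.0, config.log2_noise_sd / _SQRT2, size=2)
            heavy = base * 2.0 ** eps_h
            light = base * state_abundances[protein][state] * infl * 2.0 ** eps_l
            rows.append((protein, state, light, heavy))
    df = pd.DataFrame(rows, columns=["protein", "state",
                                     "intensity_light", "intensity_heavy"])
    truth = SimTruth(fold_changes={p: dict(v) for p, v in state_abundances.items()})
    return df, truth


# ---------------------------------------------------------------------------
# spectral counts


def generate_spectral_counts(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 1200),
    mean_count: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reproducible (protein, spc, length) table; counts Poisson around
    ``mean_count`` scaled by relative protein length."""
    if n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ConfigError("length_range must satisfy 1 <= min <= max")
    if mean_count < 0:
        raise ConfigError("mean_count must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    lam = mean_count * lengths / np.mean(lengths)
    spc = rng.poisson(lam)
    return pd.DataFrame({
        "protein": [f"P{i:03d}" for i in range(1, n_proteins + 1)],
        "spc": spc.astype(int),
        "length": lengths.astype(int),
    })


# ---------------------------------------------------------------------------
# exon / cluster cohorts


@dataclass
class ExonSimConfig:
    """Geometry and composition of a synthetic repressed-exon cohort.

    ``zone_counts`` fixes the exact number of exons per planted binding
    architecture (keys of :data:`ARCHITECTURE_ZONES`); alternatively pass
    ``zone_probabilities`` plus ``n_exons`` and counts are apportioned by
    largest remainder, so the planted composition is deterministic either
    way.  ``bps_offset_range`` places the branch adenosine that many nt
    upstream of the intron/exon boundary; ``boundary_margin`` keeps
    cluster midpoints at least that far inside their zone (set 0 to allow
    boundary-straddling clusters for edge testing).
    """

    zone_counts: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_COUNTS))
    zone_probabilities: dict | None = None
    n_exons: int | None = None
    intron_length_range: tuple[int, int] = (250, 450)
    exon_length_range: tuple[int, int] = (60, 150)
    bps_offset_range: tuple[int, int] = (20, 40)
    cluster_width_range: tuple[int, int] = (11, 31)
    delta_psi_range: tuple[float, float] = (15.0, 80.0)
    boundary_margin: int = 5
    minus_strand_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.zone_probabilities is not None:
            if self.n_exons is None or self.n_exons < 1:
                raise ConfigError("n_exons required with zone_probabilities")
            total = sum(self.zone_probabilities.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError("zone_probabilities must sum to 1")
            self.zone_counts = _apportion(self.zone_probabilities, self.n_exons)
        unknown = set(self.zone_counts) - set(ARCHITECTURE_ZONES)
        if unknown:
            raise ConfigError(f"unknown architectures in zone_counts: {sorted(unknown)}")
        if self.n_exons is None:
            self.n_exons = sum(self.zone_counts.values())
        elif self.n_exons != sum(self.zone_counts.values()):
            raise ConfigError("n_exons disagrees with sum of zone_counts")
        for name, rng_ in [("intron_length_range", self.intron_length_range),
                           ("exon_length_range", self.exon_length_range),
                           ("bps_offset_range", self.bps_offset_range),
                           ("cluster_width_range", self.cluster_width_range)]:
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ConfigError(f"{name} must satisfy 1 <= min <= max")
        if self.bps_offset_range[0] < 5:
            raise ConfigError("bps_offset_range: branch point must sit >= 5 nt into the intron")
        if self.bps_offset_range[1] > 97:
            raise ConfigError("bps_offset_range: branch point must lie within the 100-nt search window")
        if self.intron_length_range[0] < self.bps_offset_range[1] + 110:
            raise ConfigError(
                "intron_length_range too short for the requested bps_offset_range "
                "(distal zone needs > 100 nt upstream of the 3'ss)")
        if not 0 <= self.minus_strand_fraction <= 1:
            raise ConfigError("minus_strand_fraction must be in [0, 1]")
        if self.boundary_margin < 0:
            raise ConfigError("boundary_margin must be >= 0")


def _apportion(probs: dict, n: int) -> dict:
    """Largest-remainder apportionment of n exons over architecture classes."""
    quotas = {k: probs[k] * n for k in sorted(probs)}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return {k: v for k, v in counts.items() if v > 0}


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> np.ndarray:
    return rng.choice(list(alphabet), size=n)


def _place_cluster(zone: str, rng, ui: int, ex: int, di: int, bps_offset: int,
                   width: int, margin: int, exon_id: str, idx: int) -> tuple[int, int, int]:
    """Choose a sense-axis midpoint for a cluster of the given zone.

    Returns (start, end, midpoint) in sense coordinates of the locus
    [upstream intron | exon | downstream intron].  Midpoints are kept
    ``margin`` nt inside every decision boundary.
    """
    ag = ui - 2                      # first base of the terminal AG
    branch = ui - bps_offset         # branch adenosine
    half = (width - 1) // 2
    if zone == "a":
        lo = half                     # cluster start must be >= 0
        hi = ag - (101 + margin)      # dist to AG strictly > 100 + margin
        if hi < lo:
            raise GenerationError(
                f"{exon_id}: upstream intron too short for a distal-'a' cluster")
    elif zone == "b":
        lo = max(branch - (25 - margin), ag - (100 - margin))
        hi = ui - 1 - margin
        if hi < lo:
            raise GenerationError(f"{exon_id}: no room for a 'b' cluster")
    elif zone == "c":
        lo, hi = ui + margin, ui + ex - 1 - margin
        if hi < lo:
            raise GenerationError(f"{exon_id}: exon too short for a 'c' cluster")
    elif zone == "d":
        lo = ui + ex + margin
        hi = ui + ex + di - 1 - half
        if hi < lo:
            raise GenerationError(f"{exon_id}: downstream intron too short for a 'd' cluster")
    else:  # pragma: no cover
        raise GenerationError(f"unknown zone {zone!r}")
    mid = int(rng.integers(lo, hi + 1))
    start = max(0, mid - half)
    end = min(ui + ex + di, start + width)
    return start, end, mid


def generate_exon_cohort(
    config: ExonSimConfig,
) -> tuple[list[ExonModel], list[ClipCluster], dict[str, str], SimTruth]:
    """Generate exon loci, planted clusters, gene sequences and truth.

    Each exon sits on its own synthetic gene sequence laid out as
    [upstream intron | exon | downstream intron] on the plus strand
    (minus-strand loci, when requested, are exact reverse complements).
    The 100-nt 3' end of every upstream intron is free of adenosines
    except a single planted branch-point consensus (``CTCAG``) whose
    branch A sits at the recorded offset, and the intron ends in AG.
    """
    rng = np.random.default_rng(config.seed)

    arch_list: list[str] = []
    for arch in sorted(config.zone_counts):
        arch_list += [arch] * config.zone_counts[arch]
    rng.shuffle(arch_list)

    exons: list[ExonModel] = []
    clusters: list[ClipCluster] = []
    seqs: dict[str, str] = {}
    truth = SimTruth(zone_labels={}, architectures={}, bps_offsets={}, delta_psi={})

    for i, arch in enumerate(arch_list, start=1):
        exon_id = f"exon{i:04d}"
        chrom = f"gene{i:04d}"
        ui = int(rng.integers(*config.intron_length_range, endpoint=True))
        ex = int(rng.integers(*config.exon_length_range, endpoint=True))
        di = int(rng.integers(*config.intron_length_range, endpoint=True))
        bps_offset = int(rng.integers(*config.bps_offset_range, endpoint=True))
        total = ui + ex + di

        seq = _random_seq(rng, total)
        # 3' end of the upstream intron: A-free background, one planted
        # branch consensus, terminal AG (excluded from the search window).
        win_lo = ui - 100
        seq[win_lo:ui] = _random_seq(rng, 100, "CGT")
        branch = ui - bps_offset
        seq[branch - 3:branch + 2] = list(BPS_MOTIF)
        seq[ui - 2:ui] = ["A", "G"]
        seq_str = "".join(seq)

        delta_psi = float(rng.uniform(*config.delta_psi_range))
        minus = rng.random() < config.minus_strand_fraction

        placed = []
        for j, zone in enumerate(ARCHITECTURE_ZONES[arch], start=1):
            width = int(rng.integers(*config.cluster_width_range, endpoint=True))
            start, end, _ = _place_cluster(
                zone, rng, ui, ex, di, bps_offset, width,
                config.boundary_margin, exon_id, j)
            placed.append((f"{exon_id}_cl{j}", start, end, zone))

        if minus:
            seq_str = reverse_complement(seq_str)
            exon = ExonModel(
                exon_id=exon_id, chrom=chrom, strand="-",
                exon_start=di, exon_end=di + ex,
                upstream_intron_start=di + ex, upstream_intron_end=total,
                downstream_intron_start=0, downstream_intron_end=di,
                upstream_intron_3p_seq="".join(seq[ui - 100:ui]),
                delta_psi=delta_psi)
            for cid, s, e, zone in placed:
                clusters.append(ClipCluster(cluster_id=cid, chrom=chrom, strand="-",
                                            start=total - e, end=total - s,
                                            exon_id=exon_id))
                truth.zone_labels[cid] = zone
        else:
            exon = ExonModel(
                exon_id=exon_id, chrom=chrom, strand="+",
                exon_start=ui, exon_end=ui + ex,
                upstream_intron_start=0, upstream_intron_end=ui,
                downstream_intron_start=ui + ex, downstream_intron_end=total,
                upstream_intron_3p_seq="".join(seq[ui - 100:ui]),
                delta_psi=delta_psi)
            for cid, s, e, zone in placed:
                clusters.append(ClipCluster(cluster_id=cid, chrom=chrom, strand="+",
                                            start=s, end=e, exon_id=exon_id))
                truth.zone_labels[cid] = zone

        seqs[chrom] = seq_str
        exons.append(exon)
        truth.architectures[exon_id] = ARCHITECTURE_CLASS[arch]
        truth.bps_offsets[exon_id] = bps_offset
        truth.delta_psi[exon_id] = delta_psi

    return exons, clusters, seqs, truth


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mirror_cohort(
    exons: list[ExonModel],
    clusters: list[ClipCluster],
    seqs: dict[str, str],
) -> tuple[list[ExonModel], list[ClipCluster], dict[str, str]]:
    """Strand-flip an entire cohort: reverse-complement every gene and
    mirror all coordinates.  Zone labels must be invariant under this
    transformation (the classification works on the transcribed axis)."""
    new_exons, new_clusters, new_seqs = [], [], {}
    length = {e.chrom: len(seqs[e.chrom]) for e in exons}
    for e in exons:
        L = length[e.chrom]
        flip = "-" if e.strand == "+" else "+"
        new_exons.append(ExonModel(
            exon_id=e.exon_id, chrom=e.chrom, strand=flip,
            exon_start=L - e.exon_end, exon_end=L - e.exon_start,
            upstream_intron_start=L - e.upstream_intron_end,
            upstream_intron_end=L - e.upstream_intron_start,
            downstream_intron_start=L - e.downstream_intron_end,
            downstream_intron_end=L - e.downstream_intron_start,
            upstream_intron_3p_seq=e.upstream_intron_3p_seq,
            delta_psi=e.delta_psi))
        new_seqs[e.chrom] = reverse_complement(seqs[e.chrom])
    for c in clusters:
        L = length[c.chrom]
        flip = "-" if c.strand == "+" else "+"
        new_clusters.append(ClipCluster(
            cluster_id=c.cluster_id, chrom=c.chrom, strand=flip,
            start=L - c.end, end=L - c.start, exon_id=c.exon_id))
    return new_exons, new_clusters, new_seqs
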