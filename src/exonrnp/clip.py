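"""Positional classification of CLIP clusters around repressed cassette exons.

Exons repressed by the polypyrimidine-tract binding protein PTBP1 carry
iCLIP binding clusters whose position relative to the exon determines the
plausible repression mechanism.  Each cluster is assigned one zone:

* ``a`` — distal upstream intron, beyond the branch point region;
* ``b`` — branch point sequence (BPS) / polypyrimidine tract, i.e. the
  3' splice site neighborhood;
* ``c`` — within the exon;
* ``d`` — downstream intron, past the 5' splice site.

The decision uses the cluster MIDPOINT (on even lengths, the central
position nearer the 3' splice site).  Clusters more than 100 nt upstream
of the intron-terminal AG are ``a`` outright; within 100 nt the branch
adenosine is located by scanning a position-weight matrix over the
intron 3' end, and clusters more than 25 nt upstream of it are still
``a`` while the remainder are ``b``.  Distances are measured exclusively
from the first base of the terminal AG and from the branch adenosine.

All coordinates are 0-based half-open genomic intervals; minus-strand
loci are handled by mirroring onto the transcribed (sense) axis, so the
rules are written once.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ExonRnpError

ZONES = ("a", "b", "c", "d")

DISTAL_3SS_CUTOFF = 100   # nt upstream of the 3'ss AG
DISTAL_BPS_CUTOFF = 25    # nt upstream of the branch adenosine
BPS_WINDOW = 100          # nt of intron 3' end scanned for the branch point
BPS_3SS_EXCLUSION = 3     # terminal intron nt excluded from the scan (AG + 1)

# Position-weight matrix for the branch point pentamer.  The mammalian
# consensus is pyrimidine-U-n-A-g ("cucAg" in its canonical instance);
# column order A, C, G, T for positions -3..+1 around the branch adenosine.
# The matrix is data: pass any 5x4 row-stochastic array, or load one from
# JSON with load_bps_pwm().
DEFAULT_BPS_PWM = np.array([
    [0.10, 0.45, 0.10, 0.35],   # -3: pyrimidine, c in the consensus
    [0.05, 0.20, 0.05, 0.70],   # -2: U
    [0.20, 0.35, 0.15, 0.30],   # -1: weak, c in the consensus
    [0.97, 0.01, 0.01, 0.01],   #  0: the branch adenosine
    [0.10, 0.25, 0.40, 0.25],   # +1: g in the consensus
])
BPS_BRANCH_INDEX = 3  # row of the branch A within the matrix
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def load_bps_pwm(path) -> np.ndarray:
    """Load a branch-point PWM from JSON (list of rows, columns A,C,G,T)."""
    pwm = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ExonRnpError("branch-point PWM must have 4 columns (A, C, G, T)")
    return pwm


@dataclass
class ExonModel:
    """A cassette exon with its flanking introns on one genomic sequence.

    Intervals are 0-based half-open genomic coordinates.  On the plus
    strand the upstream intron lies at lower coordinates than the exon;
    on the minus strand at higher coordinates.  ``upstream_intron_3p_seq``
    is the transcribed-strand sequence of (at least) the last
    ``BPS_WINDOW`` nt of the upstream intron, ending at the exon.
    ``delta_psi`` is the change in percent-spliced-in upon regulator
    depletion, in percentage points.
    """

    exon_id: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_intron_start: int
    upstream_intron_end: int
    downstream_intron_start: int
    downstream_intron_end: int
    upstream_intron_3p_seq: str = ""
    delta_psi: float | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ExonRnpError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e, name in [
            (self.exon_start, self.exon_end, "exon"),
            (self.upstream_intron_start, self.upstream_intron_end, "upstream intron"),
            (self.downstream_intron_start, self.downstream_intron_end, "downstream intron"),
        ]:
            if e <= s:
                raise ExonRnpError(f"{name} interval of {self.exon_id} is empty or inverted")
        if self.strand == "+":
            ordered = (self.upstream_intron_end == self.exon_start
                       and self.exon_end == self.downstream_intron_start)
        else:
            ordered = (self.downstream_intron_end == self.exon_start
                       and self.exon_end == self.upstream_intron_start)
        if not ordered:
            raise ExonRnpError(
                f"intervals of {self.exon_id} are not contiguous in transcription order")

    # -- transcribed-axis geometry -------------------------------------
    @property
    def locus_start(self) -> int:
        return min(self.upstream_intron_start, self.exon_start,
                   self.downstream_intron_start)

    @property
    def locus_end(self) -> int:
        return max(self.upstream_intron_end, self.exon_end,
                   self.downstream_intron_end)

    def sense_position(self, genomic_pos: int) -> int:
        """Map a genomic position onto the transcribed axis (0 = locus 5' end)."""
        if self.strand == "+":
            return genomic_pos - self.locus_start
        return self.locus_end - 1 - genomic_pos

    @property
    def sense_exon(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.exon_start - self.locus_start,
                    self.exon_end - self.locus_start)
        return (self.locus_end - self.exon_end,
                self.locus_end - self.exon_start)

    @property
    def sense_upstream_intron_len(self) -> int:
        return self.upstream_intron_end - self.upstream_intron_start

    @property
    def ag_first_base_sense(self) -> int:
        """Transcribed-axis position of the first base of the terminal AG."""
        return self.sense_exon[0] - 2


@dataclass
class ClipCluster:
    """One iCLIP binding cluster (0-based half-open genomic interval)."""

    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_id: str | None = None
    zone: str | None = None

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ExonRnpError(f"cluster {self.cluster_id} has length < 1")


@dataclass
class BpsPrediction:
    """A predicted branch point within an intron 3' end.

    ``offset`` counts nucleotides from the intron/exon boundary back to
    the branch adenosine (the last intron base has offset 1); ``score``
    is the summed log2 odds of the PWM against a uniform background.
    """

    offset: int
    score: float
    window: tuple[int, int]  # searched candidate offsets [far, near)


@dataclass
class ExonBindingSummary:
    """Zone-label multiset and derived architecture class for one exon."""

    exon_id: str
    labels: Counter = field(default_factory=Counter)
    architecture: str = "unbound"
    has_upstream_distal: bool = False
    has_downstream: bool = False
    both_sides: bool = False
    degraded_evidence: bool = False


# ---------------------------------------------------------------------------
# branch point prediction


def predict_bps(
    seq: str,
    window: int = BPS_WINDOW,
    pwm: np.ndarray = DEFAULT_BPS_PWM,
    branch_index: int = BPS_BRANCH_INDEX,
) -> BpsPrediction:
    """Locate the branch adenosine in the 3'-terminal intron sequence.

    ``seq`` runs 5'->3' on the transcribed strand and ends at the 3' end
    of the intron.  Candidate positions are every adenosine within the
    final ``window`` nt, excluding the last ``BPS_3SS_EXCLUSION`` nt (the
    terminal AG and the base before it).  Each candidate is scored by the
    PWM centered on its branch-A row; the best score wins and ties break
    toward the 3' splice site.

    Raises :class:`ExonRnpError` when no adenosine exists in the window.
    A sequence shorter than the window is scanned in full.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    lo = max(0, n - window)
    hi = n - BPS_3SS_EXCLUSION
    if hi <= lo:
        raise ExonRnpError("intron sequence too short for branch point search")

    k = pwm.shape[0]
    best: tuple[float, int] | None = None
    for p in range(lo, hi):
        if s[p] != "A":
            continue
        w_start = p - branch_index
        w_end = w_start + k
        if w_start < 0 or w_end > n:
            continue
        score = 0.0
        valid = True
        for i, base in enumerate(s[w_start:w_end]):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                valid = False
                break
            score += float(np.log2(pwm[i, idx] / 0.25))
        if not valid:
            continue
        # ties break toward the 3'ss: >= keeps the later (nearer) position
        if best is None or score >= best[0]:
            best = (score, p)
    if best is None:
        raise ExonRnpError("no candidate branch point: no scoreable adenosine in window")
    score, p = best
    return BpsPrediction(offset=n - p, score=score, window=(n - lo, n - hi))


def predict_bps_for_exon(exon: ExonModel, **kwargs) -> BpsPrediction:
    """Branch-point prediction on an exon model's upstream-intron 3' sequence."""
    if not exon.upstream_intron_3p_seq:
        raise ExonRnpError(f"exon {exon.exon_id} carries no upstream intron sequence")
    return predict_bps(exon.upstream_intron_3p_seq, **kwargs)


# ---------------------------------------------------------------------------
# zone classification


def cluster_midpoint_sense(cluster: ClipCluster, exon: ExonModel) -> int:
    """Cluster midpoint on the transcribed axis.

    For even-length clusters the two central positions are both
    candidates; the one nearer the 3' splice site AG is used, making the
    operand deterministic.
    """
    pos = sorted(exon.sense_position(g) for g in (cluster.start, cluster.end - 1))
    lo, hi = pos
    length = hi - lo + 1
    mid_lo = lo + (length - 1) // 2
    mid_hi = lo + length // 2
    if mid_lo == mid_hi:
        return mid_lo
    ag = exon.ag_first_base_sense
    return mid_lo if abs(mid_lo - ag) <= abs(mid_hi - ag) else mid_hi


def classify_cluster(
    cluster: ClipCluster,
    exon: ExonModel,
    bps: BpsPrediction | None = None,
    distal_3ss_cutoff: int = DISTAL_3SS_CUTOFF,
    distal_bps_cutoff: int = DISTAL_BPS_CUTOFF,
    inclusive: bool = False,
) -> tuple[str, bool]:
    """Assign one zone label to a cluster; returns (zone, degraded_evidence).

    Decision sequence on the transcribed axis:

    1. midpoint inside the exon -> ``c``;
    2. midpoint past the 5' splice site -> ``d``;
    3. midpoint more than ``distal_3ss_cutoff`` nt upstream of the
       3'ss AG -> ``a``;
    4. otherwise the branch point decides: more than ``distal_bps_cutoff``
       nt upstream of the branch adenosine -> ``a``, else ``b``.

    ``inclusive`` switches the two distance comparisons from strict ``>``
    (the default, matching "more than N nt") to ``>=``.  When the branch
    point is needed but prediction failed (``bps is None`` and the exon
    sequence yields no candidate), the cluster is conservatively labelled
    ``b`` with the degraded-evidence flag set.
    """
    if cluster.chrom != exon.chrom or cluster.strand != exon.strand:
        raise ExonRnpError(
            f"cluster {cluster.cluster_id} does not share chrom/strand with exon {exon.exon_id}")
    mid = cluster_midpoint_sense(cluster, exon)
    if not (0 <= mid < exon.locus_end - exon.locus_start):
        raise ExonRnpError(
            f"cluster {cluster.cluster_id} midpoint falls outside the locus of {exon.exon_id}")

    exon_s, exon_e = exon.sense_exon
    beyond = (lambda d, c: d >= c) if inclusive else (lambda d, c: d > c)

    if exon_s <= mid < exon_e:
        return "c", False
    if mid >= exon_e:
        return "d", False

    dist_3ss = exon.ag_first_base_sense - mid
    if beyond(dist_3ss, distal_3ss_cutoff):
        return "a", False

    if bps is None:
        try:
            bps = predict_bps_for_exon(exon)
        except ExonRnpError:
            return "b", True  # unresolvable proximal cluster: treat as 3'ss-associated
    branch_sense = exon_s - bps.offset
    dist_bps = branch_sense - mid
    if beyond(dist_bps, distal_bps_cutoff):
        return "a", False
    return "b", False


def select_derepressed(
    exons: list[ExonModel],
    clusters_by_exon: dict[str, list[ClipCluster]],
    psi_threshold: float = 15.0,
) -> tuple[list[ExonModel], list[tuple[str, str]]]:
    """Retain exons derepressed by >= ``psi_threshold`` PSI points that carry clusters.

    Returns the retained exons and a log of (exon_id, reason) exclusions
    (``missing-delta-psi``, ``below-threshold`` or ``no-clusters``).
    """
    kept, log = [], []
    for exon in exons:
        if exon.delta_psi is None:
            log.append((exon.exon_id, "missing-delta-psi"))
        elif exon.delta_psi < psi_threshold:
            log.append((exon.exon_id, "below-threshold"))
        elif not clusters_by_exon.get(exon.exon_id):
            log.append((exon.exon_id, "no-clusters"))
        else:
            kept.append(exon)
    return kept, log


# ---------------------------------------------------------------------------
# per-exon and cohort summaries


def summarize_exon(exon_id: str, labels, degraded: bool = False) -> ExonBindingSummary:
    """Collapse an exon's zone labels into a binding-architecture class.

    ``distal-only``: at least one label, all in {a, d}; ``contains-b`` /
    ``contains-c``: a proximal or exonic label present (both -> ``mixed``);
    ``unbound``: no labels.
    """
    counts = Counter(labels)
    unknown = set(counts) - set(ZONES)
    if unknown:
        raise ExonRnpError(f"unknown zone labels {sorted(unknown)} for exon {exon_id}")
    if not counts:
        arch = "unbound"
    elif set(counts) <= {"a", "d"}:
        arch = "distal-only"
    elif "b" in counts and "c" in counts:
        arch = "mixed"
    elif "b" in counts:
        arch = "contains-b"
    else:
        arch = "contains-c"
    return ExonBindingSummary(
        exon_id=exon_id,
        labels=counts,
        architecture=arch,
        has_upstream_distal="a" in counts,
        has_downstream="d" in counts,
        both_sides="a" in counts and "d" in counts,
        degraded_evidence=degraded,
    )


def cohort_summary(summaries: list[ExonBindingSummary]) -> dict:
    """Counts and fractions of binding architectures over a cohort.

    Fractions are percentages rounded to 0.1; ``both_sides_of_distal``
    counts distal-only exons bound in both flanking introns.
    """
    if not summaries:
        raise ExonRnpError("empty cohort")
    n = len(summaries)
    counts = Counter(s.architecture for s in summaries)
    both = sum(1 for s in summaries if s.architecture == "distal-only" and s.both_sides)
    out = {
        "n_exons": n,
        "counts": {k: counts.get(k, 0)
                   for k in ("distal-only", "contains-b", "contains-c", "mixed", "unbound")},
        "fractions_percent": {},
        "distal_only_count": counts.get("distal-only", 0),
        "distal_only_percent": round(100.0 * counts.get("distal-only", 0) / n, 1),
        "both_sides_of_distal": both,
    }
    out["fractions_percent"] = {
        k: round(100.0 * v / n, 1) for k, v in out["counts"].items()
    }
    return out


def classify_cohort(
    exons: list[ExonModel],
    clusters: list[ClipCluster],
    psi_threshold: float | None = 15.0,
    **classify_kwargs,
) -> dict:
    """End-to-end: associate, filter, classify and summarize a cohort.

    Clusters are associated to the exon whose locus they overlap on the
    same chromosome and strand (or by their ``exon_id`` field when set).
    Returns a dict with ``clusters`` (zone-labelled), ``summaries``,
    ``cohort`` (the cohort_summary), and ``excluded`` (filter log).
    """
    by_exon: dict[str, list[ClipCluster]] = {e.exon_id: [] for e in exons}
    exon_index = {e.exon_id: e for e in exons}
    unassociated = []
    for cl in clusters:
        if cl.exon_id and cl.exon_id in exon_index:
            by_exon[cl.exon_id].append(cl)
            continue
        hit = None
        for e in exons:
            if (cl.chrom == e.chrom and cl.strand == e.strand
                    and cl.start < e.locus_end and cl.end > e.locus_start):
                hit = e
                break
        if hit is None:
            unassociated.append(cl.cluster_id)
        else:
            cl.exon_id = hit.exon_id
            by_exon[hit.exon_id].append(cl)

    if psi_threshold is not None:
        kept, log = select_derepressed(exons, by_exon, psi_threshold)
    else:
        kept = [e for e in exons if by_exon[e.exon_id]]
        log = [(e.exon_id, "no-clusters") for e in exons if not by_exon[e.exon_id]]

    bps_cache: dict[str, BpsPrediction | None] = {}
    summaries = []
    labelled: list[ClipCluster] = []
    for exon in kept:
        if exon.exon_id not in bps_cache:
            try:
                bps_cache[exon.exon_id] = predict_bps_for_exon(exon)
            except ExonRnpError:
                bps_cache[exon.exon_id] = None
        degraded = False
        labels = []
        for cl in by_exon[exon.exon_id]:
            zone, flag = classify_cluster(cl, exon, bps=bps_cache[exon.exon_id],
                                          **classify_kwargs)
            cl.zone = zone
            degraded = degraded or flag
            labels.append(zone)
            labelled.append(cl)
        summaries.append(summarize_exon(exon.exon_id, labels, degraded))

    return {
        "clusters": labelled,
        "summaries": summaries,
        "cohort": cohort_summary(summaries) if summaries else None,
        "excluded": log,
        "unassociated_clusters": unassociated,
        "bps": bps_cache,
    }
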