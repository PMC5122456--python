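"""Per-protein SILAC ratio computation and anchor normalization.

A three-state comparison of exon ribonucleoprotein (RNP) complexes —
a splicing-repressed complex, an active early complex, and the exon
definition complex (EDC) — is quantified by mixing pairs of purified
complexes assembled in light (12C) and heavy (13C Arg/Lys) nuclear
extract and measuring light/heavy peptide intensity ratios.

The cap-binding proteins CBP20 and CBP80 bind every capped substrate RNA
once, so they are present at equal molar amounts in all complexes.  Their
averaged SILAC ratio measures the mixing/processing error of an experiment,
and dividing every protein's ratio by it removes that error ("anchor
normalization").  Two derived quantities follow:

* direct fold changes — for a mixture of state A (light) with state B
  (heavy), the anchor-normalized ratio of a protein *is* its A/B fold
  change;
* ratio-of-ratios — dividing normalized EDC/repressed ratios by
  normalized active/repressed ratios cancels the repressed-state term and
  estimates EDC/active fold changes without a direct EDC-vs-active mixture.

A second, spiked-reference design is also supported: three light complexes
are each spiked with one common heavy reference mixture, and per-complex
abundances are obtained by normalizing each light/heavy ratio to the
anchor ratios of the same mixture.

All tables are pandas DataFrames.  Peptide tables carry the columns
``peptide, protein, complex_pair, intensity_light, intensity_heavy``;
absent channel measurements are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NoAnchorError

DEFAULT_ANCHORS = ("CBP20", "CBP80")

#: enrichment classes assigned by :func:`classify_enrichment`
ENRICHED = "enriched"
DEPLETED = "depleted"
UNCHANGED = "unchanged"
INSUFFICIENT = "insufficient-evidence"

PEPTIDE_COLUMNS = ["peptide", "protein", "complex_pair",
                   "intensity_light", "intensity_heavy"]


@dataclass
class ComplexComparison:
    """Fold changes for one pairwise comparison of complex states.

    ``numerator``/``denominator`` record the orientation (which state the
    fold change counts up in); ``table`` holds one row per protein with
    columns ``fold_change`` and ``enrichment_class`` plus whatever ratio
    columns the comparison was derived from.
    """

    label: str
    numerator: str
    denominator: str
    table: pd.DataFrame = field(repr=False)

    def reversed(self, threshold: float = 2.0) -> "ComplexComparison":
        """Same comparison with numerator and denominator swapped (f -> 1/f)."""
        t = self.table.copy()
        defined = t["fold_change"].notna()
        t.loc[defined, "fold_change"] = 1.0 / t.loc[defined, "fold_change"]
        t.loc[defined, "enrichment_class"] = [
            classify_enrichment(f, threshold) for f in t.loc[defined, "fold_change"]
        ]
        return ComplexComparison(
            label=f"{self.denominator}_vs_{self.numerator}",
            numerator=self.denominator,
            denominator=self.numerator,
            table=t,
        )


# ---------------------------------------------------------------------------
# peptide -> protein ratios


def peptide_ratios(peptides: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute light/heavy ratios per peptide, excluding unusable rows.

    A peptide contributes a ratio only when both channels are present and
    strictly positive.  Excluded peptides are returned in a second frame
    with a ``reason`` column (``missing-channel`` or ``zero-channel``) so
    that no record is dropped silently.
    """
    df = peptides.copy()
    light = df["intensity_light"]
    heavy = df["intensity_heavy"]
    missing = light.isna() | heavy.isna()
    zero = ~missing & ((light <= 0) | (heavy <= 0))
    ok = ~missing & ~zero

    dropped = df.loc[missing | zero].copy()
    dropped["reason"] = np.where(missing.loc[dropped.index], "missing-channel",
                                 "zero-channel")

    ratios = df.loc[ok].copy()
    ratios["ratio"] = ratios["intensity_light"] / ratios["intensity_heavy"]
    return ratios, dropped


def aggregate_protein_ratios(
    ratios: pd.DataFrame,
    method: str = "median",
    min_peptides: int = 1,
) -> pd.DataFrame:
    """Aggregate peptide ratios to one raw ratio per (protein, complex_pair).

    Aggregation happens in log2 space — the median (default, robust to
    single-peptide outliers) or the mean of log2 peptide ratios is
    exponentiated back to a ratio.  ``n_peptides`` counts the peptides
    actually used.  Proteins with fewer than ``min_peptides`` valid
    peptides are omitted (default keeps everything with >= 1).
    """
    if method not in ("median", "mean"):
        raise ConfigError(f"aggregation method must be 'median' or 'mean', got {method!r}")
    if ratios.empty:
        return pd.DataFrame(columns=["protein", "complex_pair", "raw_ratio", "n_peptides"])

    log2r = np.log2(ratios["ratio"].to_numpy())
    work = ratios.assign(_log2=log2r)
    agg = np.median if method == "median" else np.mean
    rows = []
    for (protein, pair), grp in work.groupby(["protein", "complex_pair"], sort=True):
        if len(grp) < min_peptides:
            continue
        rows.append((protein, pair, float(2.0 ** agg(grp["_log2"])), len(grp)))
    return pd.DataFrame(rows, columns=["protein", "complex_pair", "raw_ratio", "n_peptides"])


# ---------------------------------------------------------------------------
# anchor normalization


def _anchor_average(values: np.ndarray, method: str) -> float:
    if method == "geometric":
        return float(2.0 ** np.mean(np.log2(values)))
    if method == "arithmetic":
        return float(np.mean(values))
    raise ConfigError(f"anchor averaging method must be 'geometric' or 'arithmetic', got {method!r}")


def anchor_normalize(
    table: pd.DataFrame,
    anchor_ids=DEFAULT_ANCHORS,
    ratio_column: str = "raw_ratio",
    method: str = "geometric",
) -> pd.DataFrame:
    """Divide every ratio by the averaged ratio of the anchor proteins.

    The anchors (cap-binding proteins by default) are equimolar in every
    complex, so their average ratio estimates the global mixing error.
    Averaging is geometric by default (ratios are multiplicative); after
    normalization the geometric mean of anchor ratios is exactly 1.

    Raises :class:`NoAnchorError` when no anchor is present; warns when
    only a single anchor carries the normalization.
    """
    anchors = table.loc[table["protein"].isin(set(anchor_ids))]
    if anchors.empty:
        raise NoAnchorError(
            f"no anchor proteins found (looked for {sorted(set(anchor_ids))})")
    if anchors["protein"].nunique() == 1:
        warnings.warn(
            f"only one anchor protein present ({anchors['protein'].iloc[0]}); "
            "normalizing on a single anchor", stacklevel=2)

    out = table.copy()
    if "complex_pair" in table.columns and table["complex_pair"].nunique() > 1:
        norm = []
        for pair, grp in out.groupby("complex_pair", sort=False):
            anc = grp.loc[grp["protein"].isin(set(anchor_ids)), ratio_column]
            if anc.empty:
                raise NoAnchorError(f"no anchor proteins found in comparison {pair!r}")
            factor = _anchor_average(anc.to_numpy(), method)
            norm.append(grp[ratio_column] / factor)
        out["normalized_ratio"] = pd.concat(norm).reindex(out.index)
    else:
        factor = _anchor_average(anchors[ratio_column].to_numpy(), method)
        out["normalized_ratio"] = out[ratio_column] / factor
    return out


# ---------------------------------------------------------------------------
# fold changes


def classify_enrichment(fold_change: float, threshold: float = 2.0) -> str:
    """Two-fold rule: enriched above ``threshold``, depleted below its inverse."""
    if not np.isfinite(fold_change) or fold_change <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fold_change}")
    if threshold <= 1:
        raise ConfigError(f"threshold must exceed 1, got {threshold}")
    if fold_change > threshold:
        return ENRICHED
    if fold_change < 1.0 / threshold:
        return DEPLETED
    return UNCHANGED


def fold_change(
    table: pd.DataFrame,
    numerator: str,
    denominator: str,
    threshold: float = 2.0,
) -> ComplexComparison:
    """Turn a normalized ratio table for a direct mixture into fold changes.

    For a mixture with state ``numerator`` in the light channel and state
    ``denominator`` in the heavy channel, the normalized light/heavy ratio
    is itself the numerator/denominator fold change; this function attaches
    the orientation metadata and an enrichment class per protein.
    """
    t = table.copy()
    t["fold_change"] = t["normalized_ratio"]
    t["enrichment_class"] = [
        classify_enrichment(f, threshold) if np.isfinite(f) and f > 0 else INSUFFICIENT
        for f in t["fold_change"].fillna(np.nan)
    ]
    return ComplexComparison(
        label=f"{numerator}_vs_{denominator}",
        numerator=numerator, denominator=denominator, table=t,
    )


def ratio_of_ratios(
    numerator_table: pd.DataFrame,
    denominator_table: pd.DataFrame,
    label: str = "edc_vs_active",
    numerator: str = "edc",
    denominator: str = "active",
    threshold: float = 2.0,
) -> tuple[ComplexComparison, pd.DataFrame]:
    """Divide two normalized ratio tables sharing a common reference state.

    With EDC/repressed ratios in the numerator table and active/repressed
    ratios in the denominator table, the repressed terms cancel and the
    quotient estimates EDC/active fold changes.  Proteins present in only
    one table cannot be divided; they are returned separately (never
    silently dropped).
    """
    a = numerator_table.set_index("protein")["normalized_ratio"]
    b = denominator_table.set_index("protein")["normalized_ratio"]
    common = a.index.intersection(b.index)
    only = a.index.symmetric_difference(b.index)

    fc = (a.loc[common] / b.loc[common]).rename("fold_change")
    t = fc.reset_index()
    t["enrichment_class"] = [classify_enrichment(f, threshold) for f in t["fold_change"]]
    omitted = pd.DataFrame({
        "protein": list(only),
        "reason": ["present-in-one-table"] * len(only),
    })
    comp = ComplexComparison(label=label, numerator=numerator,
                             denominator=denominator, table=t)
    return comp, omitted


# ---------------------------------------------------------------------------
# spiked-reference design


def reference_channel_abundance(
    intensities: pd.DataFrame,
    anchor_ids=DEFAULT_ANCHORS,
) -> pd.DataFrame:
    """Per-complex relative abundances from a common heavy spike-in.

    ``intensities`` has one row per (protein, state) with columns
    ``protein, state, intensity_light, intensity_heavy``, where the heavy
    channel is the shared reference mixture.  For each state *s* and
    protein *p*::

        abundance(p, s) = [L(p,s) / H(p,s)] / geomean over anchors of [L(a,s) / H(a,s)]

    so anchors sit at 1 in every state and loading/mixing inflation of a
    state cancels.  Proteins lacking a heavy reference measurement are
    classed ``insufficient-evidence`` (abundance NaN).
    """
    df = intensities.copy()
    ok = df["intensity_heavy"].notna() & (df["intensity_heavy"] > 0) \
        & df["intensity_light"].notna() & (df["intensity_light"] >= 0)
    df["ratio"] = np.where(ok, df["intensity_light"] / df["intensity_heavy"], np.nan)

    out = []
    for state, grp in df.groupby("state", sort=True):
        anc = grp.loc[grp["protein"].isin(set(anchor_ids)) & grp["ratio"].notna(),
                      "ratio"]
        if anc.empty:
            raise NoAnchorError(f"no anchor proteins with reference signal in state {state!r}")
        factor = float(2.0 ** np.mean(np.log2(anc.to_numpy())))
        g = grp.copy()
        g["abundance"] = g["ratio"] / factor
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    res["evidence"] = np.where(res["abundance"].notna(), "quantified", INSUFFICIENT)
    return res[["protein", "state", "abundance", "evidence"]]


def abundance_fold_change(
    abundances: pd.DataFrame,
    numerator_state: str,
    denominator_state: str,
    threshold: float = 2.0,
) -> ComplexComparison:
    """State-vs-state fold changes as ratios of spiked-reference abundances."""
    wide = abundances.pivot(index="protein", columns="state", values="abundance")
    for s in (numerator_state, denominator_state):
        if s not in wide.columns:
            raise KeyError(f"state {s!r} absent from abundance table")
    fc = wide[numerator_state] / wide[denominator_state]
    t = fc.rename("fold_change").reset_index()
    t["enrichment_class"] = [
        classify_enrichment(f, threshold) if np.isfinite(f) and f > 0 else INSUFFICIENT
        for f in t["fold_change"]
    ]
    return ComplexComparison(
        label=f"{numerator_state}_vs_{denominator_state}",
        numerator=numerator_state, denominator=denominator_state, table=t,
    )


# ---------------------------------------------------------------------------
# cross-experiment filter


def consistency_filter(
    comparison_a: ComplexComparison,
    comparison_b: ComplexComparison,
) -> pd.DataFrame:
    """Keep only proteins quantified in both independent experiments.

    Proteins observed in a single experiment are not considered further.
    For each retained protein both fold changes are reported together with
    an ``agreement`` flag: True when the two estimates fall on the same
    side of 1 (both up or both down).
    """
    a = comparison_a.table.dropna(subset=["fold_change"]).set_index("protein")["fold_change"]
    b = comparison_b.table.dropna(subset=["fold_change"]).set_index("protein")["fold_change"]
    common = a.index.intersection(b.index)
    if common.empty:
        warnings.warn("no proteins shared between the two experiments", stacklevel=2)
    out = pd.DataFrame({
        "protein": common,
        "fold_change_exp1": a.loc[common].to_numpy(),
        "fold_change_exp2": b.loc[common].to_numpy(),
    })
    out["agreement"] = (out["fold_change_exp1"] >= 1) == (out["fold_change_exp2"] >= 1)
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience


def quantify_experiment(
    peptides: pd.DataFrame,
    anchor_ids=DEFAULT_ANCHORS,
    aggregation: str = "median",
    anchor_method: str = "geometric",
    threshold: float = 2.0,
    min_peptides: int = 1,
) -> dict:
    """Peptide table -> normalized per-pair ratio tables and fold changes.

    Runs peptide_ratios -> aggregate_protein_ratios -> anchor_normalize for
    every ``complex_pair`` present, derives direct fold changes per pair
    (numerator/denominator parsed from the ``A_vs_B`` pair label), and —
    when both ``edc_vs_repressed`` and ``active_vs_repressed`` mixtures are
    present — the derived ``edc_vs_active`` ratio-of-ratios comparison.

    Returns a dict with keys ``ratios`` (per-pair normalized tables),
    ``comparisons`` (label -> ComplexComparison) and ``dropped_peptides``.
    """
    ratios, dropped = peptide_ratios(peptides)
    agg = aggregate_protein_ratios(ratios, method=aggregation, min_peptides=min_peptides)

    tables: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, ComplexComparison] = {}
    for pair, grp in agg.groupby("complex_pair", sort=True):
        table = anchor_normalize(grp, anchor_ids, method=anchor_method)
        tables[pair] = table.reset_index(drop=True)
        num, _, den = pair.partition("_vs_")
        comparisons[pair] = fold_change(tables[pair], num, den or "reference",
                                        threshold=threshold)

    if {"edc_vs_repressed", "active_vs_repressed"} <= tables.keys():
        derived, _ = ratio_of_ratios(
            tables["edc_vs_repressed"], tables["active_vs_repressed"],
            threshold=threshold)
        comparisons["edc_vs_active"] = derived

    return {"ratios": tables, "comparisons": comparisons, "dropped_peptides": dropped}
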