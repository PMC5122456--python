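"""Small quantifications of gel band intensities.

Band intensities are numeric inputs (densitometry is out of scope).
``rna_stoichiometry`` converts band intensities of stained RNA species
to molar ratios: staining scales with length, so intensity divided by
nucleotide length is proportional to molar amount, reported relative to
a reference band (the substrate exon RNA).  ``percent_inclusion``
quantifies cassette-exon splicing from included/skipped product bands.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class BandMeasurement:
    """One quantified gel band; ``length`` (nt) is needed only for stoichiometry."""

    band: str
    intensity: float
    length: int | None = None

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError(f"band {self.band}: intensity must be >= 0")
        if self.length is not None and self.length < 1:
            raise ValueError(f"band {self.band}: length must be >= 1")


def rna_stoichiometry(bands: list[BandMeasurement], reference: str) -> dict[str, float]:
    """Molar ratio of each band relative to the reference band.

    ratio(b) = (I_b / L_b) / (I_ref / L_ref); the reference maps to 1,
    a band of zero intensity to 0 (species absent from the complex).
    """
    by_name = {b.band: b for b in bands}
    if reference not in by_name:
        raise KeyError(f"reference band {reference!r} not measured")
    ref = by_name[reference]
    if ref.intensity <= 0:
        raise ValueError("reference band intensity must be > 0")
    if ref.length is None:
        raise ValueError("reference band needs a nucleotide length")
    ref_molar = ref.intensity / ref.length
    out = {}
    for b in bands:
        if b.length is None:
            raise ValueError(f"band {b.band} needs a nucleotide length")
        out[b.band] = (b.intensity / b.length) / ref_molar
    return out


def band_ratio(numerator: BandMeasurement, denominator: BandMeasurement) -> float:
    """Simple intensity ratio of two bands (e.g. EDC over early exon RNP)."""
    if denominator.intensity <= 0:
        raise ValueError(f"denominator band {denominator.band} has zero intensity")
    return numerator.intensity / denominator.intensity


def band_ratio_series(
    pairs: dict[float, tuple[BandMeasurement, BandMeasurement]],
) -> list[tuple[float, float]]:
    """Band ratios over labeled time points, ordered by time."""
    return [(t, band_ratio(*pairs[t])) for t in sorted(pairs)]


def percent_inclusion(included: BandMeasurement, skipped: BandMeasurement) -> float:
    """Percent spliced-in from included and skipped product band intensities."""
    total = included.intensity + skipped.intensity
    if total <= 0:
        raise ValueError("included and skipped bands are both zero")
    return 100.0 * included.intensity / total
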