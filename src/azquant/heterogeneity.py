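"""Compartmental intensity profiles and the heterogeneity statistic H.

The measurand is the brightness of individual presynaptic Bruchpilot (Brp)
puncta. Per brain sample, the median punctum intensity M_c is computed for
each of the five γ-lobe compartments (γ1..γ5); the per-sample heterogeneity
level is

    H = sample SD (n−1 denominator) of {log₂ M_c, c = 1..5}.

Because H is a dispersion of log-medians it is invariant to global intensity
rescaling, so samples of different overall brightness are comparable, and it
is insensitive to per-compartment punctum counts (medians, not sums).

Log base 2 is the package default (matching the pseudo-colour convention
log₂(I/mean)); SD in another base differs only by a constant factor and the
base is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAMMA_COMPARTMENTS",
    "CompartmentProfile",
    "HeterogeneityResult",
    "compartment_median",
    "normalize_medians",
    "heterogeneity_sd",
    "profile_from_records",
    "pseudocolor_map",
]

GAMMA_COMPARTMENTS = ("gamma1", "gamma2", "gamma3", "gamma4", "gamma5")

_STAT_ATTR = {
    "mean": "mean_intensity",
    "sum": "sum_intensity",
    "max": "max_intensity",
    "median": "median_intensity",
}


@dataclass
class CompartmentProfile:
    """Per-sample compartment medians and their normalized profile."""

    sample_id: str
    compartments: tuple[str, ...]
    counts: np.ndarray        # clusters per compartment
    medians: np.ndarray       # M_c, NaN where a compartment is empty
    normalized: np.ndarray    # M̃_c = M_c / mean_c(M_c)
    statistic: str = "mean"   # per-cluster statistic the medians summarise

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.medians).all())


@dataclass
class HeterogeneityResult:
    """Per-sample H = SD of log-transformed compartment medians."""

    sample_id: str
    H: float
    log_medians: np.ndarray
    log_base: float = 2.0
    variance: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.variance):
            self.variance = float(self.H) ** 2


def compartment_median(
    records: Iterable,
    compartment: str | int,
    statistic: str = "mean",
) -> float:
    """Median over a compartment's clusters of a chosen per-cluster statistic.

    ``statistic`` selects which per-cluster intensity summary enters the
    median: ``mean`` (default; robust to cluster volume), ``sum``, ``max`` or
    ``median``. An even cluster count yields the mean of the two central
    values. Raises on an empty compartment — callers flag and exclude the
    sample instead of silently imputing.
    """
    attr = _STAT_ATTR[statistic]
    values = [getattr(r, attr) for r in records if r.compartment == compartment]
    if not values:
        raise ValueError(f"compartment {compartment!r} has no clusters")
    return float(np.median(values))


def normalize_medians(medians: Sequence[float]) -> np.ndarray:
    """Normalize compartment medians to the average of the five medians."""
    m = np.asarray(medians, dtype=float)
    if not (m > 0).all():
        raise ValueError("all compartment medians must be positive")
    return m / m.mean()


def heterogeneity_sd(
    medians: Sequence[float], log_base: float = 2.0, ddof: int = 1
) -> float:
    """Sample SD of log-transformed compartment medians (the statistic H).

    Uses the n−1 denominator. Any nonpositive or missing median is an error;
    such samples are excluded upstream.
    """
    m = np.asarray(medians, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two compartment medians")
    if not np.isfinite(m).all() or not (m > 0).all():
        raise ValueError("compartment medians must be positive and finite")
    logs = np.log(m) / np.log(log_base)
    return float(np.std(logs, ddof=ddof))


def profile_from_records(
    records: Sequence,
    sample_id: str = "",
    compartments: Sequence[str] = GAMMA_COMPARTMENTS,
    statistic: str = "mean",
    log_base: float = 2.0,
) -> tuple[CompartmentProfile, HeterogeneityResult | None]:
    """Build the compartment profile and H for one sample's cluster records.

    Returns ``(profile, result)``; ``result`` is None when any compartment is
    empty (H is undefined without all five medians) and the profile's
    ``normalized`` entries are NaN in that case.
    """
    attr = _STAT_ATTR[statistic]
    medians = np.full(len(compartments), np.nan)
    counts = np.zeros(len(compartments), dtype=int)
    for i, comp in enumerate(compartments):
        vals = [getattr(r, attr) for r in records if r.compartment == comp]
        counts[i] = len(vals)
        if vals:
            medians[i] = np.median(vals)
    complete = np.isfinite(medians).all() and (medians > 0).all()
    normalized = medians / medians.mean() if complete else np.full_like(medians, np.nan)
    profile = CompartmentProfile(
        sample_id, tuple(compartments), counts, medians, normalized, statistic
    )
    if not complete:
        return profile, None
    H = heterogeneity_sd(medians, log_base=log_base)
    logs = np.log(medians) / np.log(log_base)
    return profile, HeterogeneityResult(sample_id, H, logs, log_base)


def pseudocolor_map(
    volume: np.ndarray,
    lobe_mask: np.ndarray,
    display_range: float = 1.0,
) -> np.ndarray:
    """log₂(I / mean I over the lobe mask), clipped to ±display_range.

    Zero-intensity voxels map to the lower clip; voxels outside the mask are
    NaN (rendered transparent). The lobe mean is computed over the full mask,
    signal-positive or not.
    """
    if display_range <= 0:
        raise ValueError("display_range must be positive")
    mask = np.asarray(lobe_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lobe mask")
    vol = np.asarray(volume, dtype=float)
    mean = vol[mask].mean()
    if mean <= 0:
        raise ValueError("lobe mean intensity is nonpositive")
    out = np.full(vol.shape, np.nan)
    with np.errstate(divide="ignore"):
        out[mask] = np.log2(vol[mask] / mean)
    out[mask & (vol == 0)] = -display_range
    return np.clip(out, -display_range, display_range, out=out)


def save_pseudocolor_png(
    pmap: np.ndarray, path, display_range: float = 1.0, z: str | int = "max"
):
    """Render a pseudo-colour map (or its max-projection) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.nanmax(pmap, axis=0) if z == "max" else pmap[int(z)]
    fig, ax = plt.subplots(figsize=(6, 6 * img.shape[0] / img.shape[1]))
    im = ax.imshow(img, cmap="RdBu_r", vmin=-display_range, vmax=display_range)
    fig.colorbar(im, ax=ax, label="log2(I / lobe mean)")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
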