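"""Smooth cline fitting and displacement analysis.

Allele frequencies observed along the unit transect are smoothed with a
penalized cubic B-spline regression (rich basis, likelihood-based penalty
selection), and the fitted curve is summarized by:

* the **center**, where the fit crosses frequency 0.5 (midpoint of the
  outermost crossings if the smoother wiggles through 0.5 more than once;
  if the fit sits entirely above 0.5 the cline has exited the transect
  toward the recessive-homozygote side and the center is 0, and
  symmetrically 1 if entirely below);
* the **width**, the distance between the outermost crossings of 0.1 and
  0.9 (the "eightieth percentile" definition); a threshold that is never
  reached is replaced by the nearer transect boundary and flagged;
* a **movement class**: displaced toward the recessive homozygote
  (RH, center < 0.45), spatially stable (S, 0.45-0.55), or displaced
  toward the dominant homozygote (DH, center > 0.55).

Orientation convention: the dominant (allele-1) frequency increases with
transect location at generation 0, so clines rise from left to right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.gam.api import BSplines, GLMGam

from .simulator import Snapshot

__all__ = [
    "ClinePoints",
    "ClineFitter",
    "allele_frequency_points",
    "fit_cline",
    "cline_center",
    "cline_width",
    "classify_movement",
    "displacement",
    "wilcoxon_displacement_test",
]

LOCUS_CLASSES = ("mating", "neutral")

# movement-class cut points (continuous version of the printed bins)
RH_UPPER = 0.45
DH_LOWER = 0.55


@dataclass
class ClinePoints:
    """Per-individual allele frequencies along the transect."""

    locations: np.ndarray
    frequencies: np.ndarray
    locus_class: str = "mating"

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.locations.shape != self.frequencies.shape:
            raise ValueError("locations and frequencies must be equal length")
        if self.frequencies.size and (self.frequencies.min() < 0
                                      or self.frequencies.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")


def allele_frequency_points(snapshot: Snapshot,
                            locus_class: str) -> ClinePoints:
    """Per-individual frequency (mean dosage over a locus class / 2)."""
    if locus_class not in LOCUS_CLASSES:
        raise ValueError(f"unknown locus class {locus_class!r}")
    if snapshot.locations.size == 0:
        raise ValueError("empty snapshot")
    freq = (snapshot.mating_freq if locus_class == "mating"
            else snapshot.neutral_freq)
    return ClinePoints(snapshot.locations, freq, locus_class)


def _crossings(grid: np.ndarray, pred: np.ndarray,
               level: float) -> np.ndarray:
    """Locations where the fitted curve crosses ``level`` (linear interp)."""
    d = pred - level
    exact = grid[d == 0.0]
    s = np.sign(d)
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    frac = -d[idx] / (d[idx + 1] - d[idx])
    between = grid[idx] + frac * (grid[idx + 1] - grid[idx])
    return np.sort(np.concatenate([exact, between]))


class ClineFitter(BaseEstimator):
    """Penalized-spline smoother of allele frequency on transect location.

    A cubic B-spline basis (``n_splines`` functions spanning [0, 1]) is fit
    with a second-derivative penalty whose weight is chosen on a log grid by
    the ``criterion`` of the Gaussian fit (AIC by default).  Predictions are
    evaluated on an even grid and clamped to [0, 1].

    Fitted attributes
    -----------------
    grid_ : evenly spaced prediction locations
    predictions_ : fitted frequencies on the grid, clamped to [0, 1]
    alpha_ : selected penalty weight
    center_ : 0.5-crossing location (see module docstring)
    width_ : 0.1-0.9 crossing distance
    width_flagged_ : True if a threshold was substituted by a boundary
    """

    def __init__(self, n_splines: int = 30, degree: int = 3,
                 alphas: Optional[Sequence[float]] = None,
                 criterion: str = "aic", grid_size: int = 1001,
                 min_points: int = 20, min_span: float = 0.5):
        self.n_splines = n_splines
        self.degree = degree
        self.alphas = alphas
        self.criterion = criterion
        self.grid_size = grid_size
        self.min_points = min_points
        self.min_span = min_span

    def fit(self, X, y) -> "ClineFitter":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("non-finite inputs")
        if x.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} points")
        if np.ptp(x) == 0:
            raise ValueError("degenerate input: all locations identical")
        if np.ptp(x) < self.min_span:
            raise ValueError(
                f"locations must span at least {self.min_span} of the transect")

        if np.ptp(y) == 0.0:
            # constant frequencies (e.g. a fixed locus): the smooth is flat
            self.alpha_ = np.inf
            self.result_ = None
            self.grid_ = np.linspace(0.0, 1.0, self.grid_size)
            self.predictions_ = np.full(self.grid_size,
                                        np.clip(y[0], 0.0, 1.0))
            self.center_ = cline_center(self)
            self.width_, self.width_flagged_ = _width_with_flag(self)
            return self

        basis = BSplines(x, df=[self.n_splines], degree=[self.degree],
                         knot_kwds=[{"lower_bound": 0.0, "upper_bound": 1.0}])
        alphas = (np.logspace(-7, 7, 15) if self.alphas is None
                  else np.asarray(self.alphas, dtype=float))
        best = None
        for alpha in alphas:
            res = GLMGam(y, smoother=basis, alpha=[alpha]).fit()
            score = getattr(res, self.criterion)
            if best is None or score < best[0]:
                best = (score, alpha, res)
        self.alpha_ = float(best[1])
        self.result_ = best[2]
        self.grid_ = np.linspace(0.0, 1.0, self.grid_size)
        self.predictions_ = np.clip(
            self.result_.predict(exog_smooth=self.grid_), 0.0, 1.0)
        self.center_ = cline_center(self)
        self.width_, self.width_flagged_ = _width_with_flag(self)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        if self.result_ is None:
            return np.full(x.shape, self.predictions_[0])
        return np.clip(self.result_.predict(exog_smooth=x), 0.0, 1.0)


def fit_cline(points: ClinePoints, **kwargs) -> ClineFitter:
    """Fit a smooth cline to per-individual frequency points."""
    return ClineFitter(**kwargs).fit(points.locations, points.frequencies)


def cline_center(fit: ClineFitter) -> float:
    """Location where the fitted cline crosses frequency 0.5.

    Multiple crossings collapse to the midpoint of the outermost two.  A
    fit entirely above 0.5 means the transition has exited toward the
    recessive-homozygote (left) end: center 0.  Entirely below: center 1.
    """
    xs = _crossings(fit.grid_, fit.predictions_, 0.5)
    if xs.size == 0:
        return 0.0 if fit.predictions_.min() > 0.5 else 1.0
    return float(0.5 * (xs[0] + xs[-1]))


def _width_with_flag(fit: ClineFitter) -> Tuple[float, bool]:
    lo = _crossings(fit.grid_, fit.predictions_, 0.1)
    hi = _crossings(fit.grid_, fit.predictions_, 0.9)
    flagged = False
    if lo.size:
        x10 = lo[0]
    else:  # never drops to 0.1: substitute the left boundary
        x10, flagged = 0.0, True
    if hi.size:
        x90 = hi[-1]
    else:  # never reaches 0.9: substitute the right boundary
        x90, flagged = 1.0, True
    return float(max(x90 - x10, 0.0)), flagged


def cline_width(fit: ClineFitter) -> float:
    """Distance between the outermost 0.1 and 0.9 crossings."""
    return _width_with_flag(fit)[0]


def classify_movement(center: float) -> str:
    """Movement class of a final cline center: 'RH', 'S' or 'DH'."""
    if not (0.0 <= center <= 1.0):
        raise ValueError("center outside [0, 1]")
    if center < RH_UPPER:
        return "RH"
    if center <= DH_LOWER:
        return "S"
    return "DH"


def displacement(center_mating: float, center_neutral: float) -> float:
    """Signed displacement of the mating cline from the neutral background.

    Positive values point toward the dominant-homozygote (right) side.
    """
    for c in (center_mating, center_neutral):
        if not (0.0 <= c <= 1.0):
            raise ValueError("center outside [0, 1]")
    return center_mating - center_neutral


def wilcoxon_displacement_test(centers_mating, centers_neutral) -> float:
    """One-sided paired Wilcoxon signed-rank test (mating > neutral).

    Zero differences are discarded (classical zero handling); the exact
    null distribution is used for up to 25 non-zero untied differences,
    otherwise a tie-corrected normal approximation with continuity
    correction.  All differences zero returns p = 1 (no evidence).
    """
    x = np.asarray(centers_mating, dtype=float)
    y = np.asarray(centers_neutral, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired lists must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    if n <= 25 and np.unique(absd).size == n:
        return float(stats.wilcoxon(d, alternative="greater",
                                    zero_method="wilcox",
                                    method="exact").pvalue)
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(absd, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))
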