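"""Radiocarbon chronology: filtering, calibration, date comparison.

The chronological backbone of a wave-of-advance analysis is a set of
first-arrival dates, one per site. Determinations are screened (AMS
only, standard error at most 500 yr, unequivocal cultural attribution,
older than a radiocarbon-age cutoff) and reduced to the single oldest
date per site. Each surviving date is calibrated against a calibration
curve by exact grid integration, and calibrated dates are compared
through their full densities: the distribution of the difference of two
dates (assuming independence) and the probability that one predates the
other. These are the same mathematical objects OxCal's Difference and
Order queries estimate by MCMC, computed here deterministically on the
calendar-age grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationRangeError, NoDatesError, ParameterError


@dataclass(frozen=True)
class RadiocarbonDate:
    """One radiocarbon determination tied to a site and a cultural label.

    ``equivocal`` flags contexts whose attribution is uncertain (for
    example "Aurignacian/Gravettian" or "Gravettian?"); these are
    excluded from chronology building.
    """

    site_name: str
    site_code: str
    lon: float
    lat: float
    c14_age: float
    c14_se: float
    method: str  # "AMS" | "conventional"
    attribution: str = ""
    equivocal: bool = False

    def __post_init__(self) -> None:
        if self.c14_se <= 0:
            raise ParameterError(f"{self.site_name}: c14_se must be > 0")
        if self.c14_age <= 0:
            raise ParameterError(f"{self.site_name}: c14_age must be > 0")
        if not -90.0 <= self.lat <= 90.0:
            raise ParameterError(f"{self.site_name}: latitude out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ParameterError(f"{self.site_name}: longitude out of range")


@dataclass
class CalibrationCurve:
    """A calibration curve on an ascending calendar-age grid.

    ``c14_mu`` and ``c14_sigma`` give the curve's radiocarbon age and
    its 1-sigma uncertainty at each calendar age in ``cal_bp``.
    """

    cal_bp: np.ndarray
    c14_mu: np.ndarray
    c14_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_mu = np.asarray(self.c14_mu, dtype=float)
        self.c14_sigma = np.asarray(self.c14_sigma, dtype=float)
        n = self.cal_bp.size
        if n < 2 or self.c14_mu.size != n or self.c14_sigma.size != n:
            raise ParameterError("curve grids must have equal length >= 2")
        d = np.diff(self.cal_bp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ParameterError("cal_bp grid must be strictly monotone")
        if np.any(self.c14_sigma <= 0):
            raise ParameterError("c14_sigma must be positive everywhere")
        if d[0] < 0:  # store ascending
            self.cal_bp = self.cal_bp[::-1].copy()
            self.c14_mu = self.c14_mu[::-1].copy()
            self.c14_sigma = self.c14_sigma[::-1].copy()


@dataclass
class CalibratedDensity:
    """Probability distribution of calendar age for one date.

    ``p`` is probability mass per grid point (sums to 1);
    ``mean_cal_bp`` is the expectation, the "mean calibrated age" used
    as a site's point chronology.
    """

    cal_bp: np.ndarray
    p: np.ndarray
    mean_cal_bp: float = field(init=False)

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ParameterError("density mass must be non-negative")
        total = self.p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"density mass sums to {total}, not 1")
        self.mean_cal_bp = float(np.dot(self.cal_bp, self.p))

    @property
    def median_cal_bp(self) -> float:
        cdf = np.cumsum(self.p)
        i = int(np.searchsorted(cdf, 0.5))
        return float(self.cal_bp[min(i, self.cal_bp.size - 1)])

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.cal_bp)))


@dataclass(frozen=True)
class IntervalEstimate:
    """A (lo, hi) interval in years holding `level` probability mass."""

    lo: float
    hi: float
    level: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ParameterError("interval lo must not exceed hi")


def filter_dates(
    rows: list[RadiocarbonDate], c14_cutoff: float = 27000.0
) -> list[RadiocarbonDate]:
    """Screen determinations and keep the oldest date per site.

    Rules, applied in sequence: AMS method only; standard error at most
    500 yr (501 is rejected); unequivocal attribution; radiocarbon age
    strictly older than ``c14_cutoff``; then exactly one row per site —
    the one with the largest radiocarbon age, ties resolved by smaller
    standard error and then by input order. Site order of first
    appearance is preserved.
    """
    if not rows:
        raise NoDatesError("no dates supplied")
    if c14_cutoff <= 0:
        raise ParameterError("c14_cutoff must be positive")
    kept = [
        r
        for r in rows
        if r.method == "AMS"
        and r.c14_se <= 500.0
        and not r.equivocal
        and r.c14_age > c14_cutoff
    ]
    best: dict[str, tuple[int, RadiocarbonDate]] = {}
    order: list[str] = []
    for i, r in enumerate(kept):
        key = r.site_name
        if key not in best:
            best[key] = (i, r)
            order.append(key)
            continue
        _, cur = best[key]
        if (r.c14_age, -r.c14_se) > (cur.c14_age, -cur.c14_se):
            best[key] = (best[key][0], r)
    return [best[k][1] for k in order]


def calibrate(
    d: RadiocarbonDate, curve: CalibrationCurve, step: float = 5.0
) -> CalibratedDensity:
    """Calibrate a determination by exact grid integration.

    The unnormalised posterior mass at calendar age tau is

        exp(-(x - mu(tau))^2 / (2 (se^2 + sigma(tau)^2)))

    with x the measured radiocarbon age, mu/sigma the curve interpolated
    linearly onto a calendar grid of spacing ``step``. The density is
    normalised to unit mass.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    mu_lo, mu_hi = float(curve.c14_mu.min()), float(curve.c14_mu.max())
    slack = 5.0 * (d.c14_se + float(curve.c14_sigma.max()))
    if not (mu_lo - slack <= d.c14_age <= mu_hi + slack):
        raise CalibrationRangeError(
            f"date {d.site_name} ({d.c14_age}±{d.c14_se} BP) outside curve "
            f"14C range [{mu_lo}, {mu_hi}]"
        )
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + step / 2.0, step)
    mu = np.interp(grid, curve.cal_bp, curve.c14_mu)
    sig = np.interp(grid, curve.cal_bp, curve.c14_sigma)
    var = d.c14_se**2 + sig**2
    logw = -((d.c14_age - mu) ** 2) / (2.0 * var)
    w = np.exp(logw - logw.max())
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise CalibrationRangeError(f"date {d.site_name}: zero calibrated mass")
    return CalibratedDensity(grid, w / total)


def _common_step(a: CalibratedDensity, b: CalibratedDensity) -> float:
    sa, sb = a.step, b.step
    if not np.isclose(sa, sb, rtol=1e-9, atol=1e-12):
        raise ParameterError(
            f"densities on incommensurable grids (steps {sa} and {sb})"
        )
    return sa


def difference(
    a: CalibratedDensity, b: CalibratedDensity, level: float = 0.954
) -> IntervalEstimate:
    """Highest-density interval for the age difference ``age_a - age_b``.

    The difference distribution is the discrete cross-correlation of the
    two densities (independence assumed). The returned interval is the
    smallest set of grid atoms whose mass reaches ``level``, reported as
    its [min, max] span; atoms tied at the inclusion threshold are all
    included, which makes difference(a, b) exactly the sign-flipped
    reversal of difference(b, a).
    """
    if not 0.0 < level < 1.0:
        raise ParameterError("level must lie in (0, 1)")
    step = _common_step(a, b)
    # delta grid: a.cal_bp[i] - b.cal_bp[j] spans a regular grid of the same step
    pd = np.convolve(a.p, b.p[::-1])
    lo = a.cal_bp[0] - b.cal_bp[-1]
    deltas = lo + step * np.arange(pd.size)
    order = np.argsort(-pd, kind="stable")
    csum = np.cumsum(pd[order])
    k = int(np.searchsorted(csum, level * (1.0 - 1e-12)))
    k = min(k, pd.size - 1)
    thresh = pd[order[k]]
    sel = pd >= thresh
    return IntervalEstimate(float(deltas[sel].min()), float(deltas[sel].max()), level)


def difference_density(
    a: CalibratedDensity, b: CalibratedDensity
) -> tuple[np.ndarray, np.ndarray]:
    """Full difference distribution (delta grid, mass) for plotting/inspection."""
    step = _common_step(a, b)
    pd = np.convolve(a.p, b.p[::-1])
    deltas = a.cal_bp[0] - b.cal_bp[-1] + step * np.arange(pd.size)
    return deltas, pd


def order_probability(a: CalibratedDensity, b: CalibratedDensity) -> float:
    """P(age_a > age_b) under independence, with half mass for exact ties.

    Computed in O(n log n) by accumulating b's CDF at each atom of a:
    P = sum_i p_a(tau_i) * [F_b(tau_i^-) + p_b(tau_i)/2].
    """
    cdf_b = np.concatenate([[0.0], np.cumsum(b.p)])
    left = np.searchsorted(b.cal_bp, a.cal_bp, side="left")
    right = np.searchsorted(b.cal_bp, a.cal_bp, side="right")
    below = cdf_b[left]
    ties = cdf_b[right] - cdf_b[left]
    return float(np.dot(a.p, below + 0.5 * ties))


def read_intcal(path) -> CalibrationCurve:
    """Read a calibration curve in IntCal plain-text layout.

    Columns: cal BP, 14C age BP, 1-sigma; comma- or whitespace-separated;
    lines starting with '#' are headers. Extra columns (Delta14C) are
    ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(x) for x in parts[:3]])
    if len(rows) < 2:
        raise ParameterError(f"calibration curve {path} has fewer than 2 rows")
    arr = np.asarray(rows, dtype=float)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])
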