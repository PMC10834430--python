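"""One-dimensional statistical parametric mapping (SPM).

Two-sample t-tests over smooth 1-D trajectories (e.g., a mechanical output
across the stance phase of gait), with the family-wise error controlled by
a random-field-theory (RFT) threshold: the critical t is the level at which
the expected Euler characteristic of the suprathreshold excursion set of a
smooth t-field equals the chosen alpha. Field smoothness (FWHM) is
estimated from the model residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Trajectory",
    "SPMResult",
    "resample_trajectory",
    "estimate_fwhm",
    "rft_critical_t",
    "spm_ttest2",
    "read_trajectories_csv",
    "write_result",
]

_SQRT_4LN2 = float(np.sqrt(4.0 * np.log(2.0)))


@dataclass
class Trajectory:
    """A scalar quantity sampled on a normalized 1-D domain (0-100% stance)."""

    values: np.ndarray
    nodes: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")
        if self.nodes is None:
            self.nodes = np.linspace(0.0, 100.0, len(self.values))
        else:
            self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1)
        if len(self.nodes) != len(self.values):
            raise ValueError("nodes and values length mismatch")
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")

    def __len__(self):
        return len(self.values)


@dataclass
class SPMResult:
    """Outcome of a 1-D SPM test."""

    t_curve: np.ndarray
    df: float
    fwhm_est: float
    t_critical: float
    clusters: list = field(default_factory=list)
    two_tailed: bool = True

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    @property
    def max_abs_t(self) -> float:
        return float(np.abs(self.t_curve).max())


def resample_trajectory(values, times, Q: int = 101) -> Trajectory:
    """Linear resampling onto Q equally spaced nodes over [min, max] time."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    times = np.asarray(times, dtype=np.float64).reshape(-1)
    if len(values) != len(times) or len(values) < 2:
        raise ValueError("need >= 2 (time, value) samples of equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    grid = np.linspace(times[0], times[-1], Q)
    return Trajectory(np.interp(grid, times, values), np.linspace(0, 100, Q))


def estimate_fwhm(residuals: np.ndarray) -> float:
    """RFT smoothness estimate (FWHM, in node units) from residual curves.

    The residuals are normalized to a unit-variance field node-wise; the
    FWHM of the equivalent Gaussian autocorrelation is
    sqrt(4 ln 2) / RMS gradient of that normalized field.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=np.float64))
    if len(R) < 2:
        raise ValueError("need at least 2 residual curves")
    ssq = np.sum(R**2, axis=0)
    if np.any(ssq <= 0):
        raise ValueError("zero-variance residuals: smoothness undefined")
    dx = np.diff(R / np.sqrt(ssq), axis=1)
    v = np.sum(dx**2, axis=0)  # gradient variance of the unit field, per gap
    grad_rms = float(np.sqrt(np.mean(v)))
    if grad_rms == 0:
        raise ValueError("constant residuals: smoothness undefined")
    return _SQRT_4LN2 / grad_rms


def _ec_density_t(t: float, df: float) -> float:
    """1-D Euler-characteristic density of a t field at threshold t."""
    return _SQRT_4LN2 / (2.0 * np.pi) * (1.0 + t * t / df) ** (-(df - 1.0) / 2.0)


def rft_sf(t: float, df: float, Q: int, fwhm: float) -> float:
    """P(max of the t field > t): expected-EC approximation.

    Sum of the point-process term (the field exceeds t somewhere on a set
    of measure ~0-dim) and the 1-D resel count (Q-1)/fwhm times the EC
    density. Clipped at 1.
    """
    resels = (Q - 1.0) / fwhm
    p = stats.t.sf(t, df) + resels * _ec_density_t(t, df)
    return float(min(p, 1.0))


def rft_critical_t(alpha: float = 0.05, df: float = 10, Q: int = 101, fwhm: float = 10.0, tails: int = 2) -> float:
    """Critical t at family-wise `alpha` for a smooth 1-D t field.

    Solves rft_sf(t) = alpha/tails by bisection to 1e-6. In the infinitely
    smooth limit (resels -> 0) this reduces to the ordinary Student-t
    quantile, two-tailed for tails=2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1 or fwhm <= 0 or Q < 2:
        raise ValueError("need df >= 1, fwhm > 0, Q >= 2")
    target = alpha / tails
    lo = float(stats.t.isf(target, df))  # RFT threshold can only be higher
    hi = lo + 1.0
    while rft_sf(hi, df, Q, fwhm) > target:
        hi += 5.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the RFT threshold")
    return float(optimize.brentq(lambda t: rft_sf(t, df, Q, fwhm) - target, lo, hi, xtol=1e-6))


def _suprathreshold_clusters(stat: np.ndarray, threshold: float) -> list:
    """Maximal runs of nodes with stat > threshold, as (start, end) inclusive."""
    above = stat > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(stat) - 1)
    return list(zip(starts, ends))


def spm_ttest2(
    group_a,
    group_b,
    alpha: float = 0.05,
    two_tailed: bool = True,
    equal_var: bool = True,
) -> SPMResult:
    """Two-sample SPM t-test across the whole 1-D domain.

    Node-wise pooled-variance t statistic (Welch with ``equal_var=False``),
    residual-based FWHM estimate, RFT critical threshold at `alpha`
    (split across tails when two-tailed), and suprathreshold clusters of
    |t| (or t, one-tailed).
    """
    A = np.vstack([t.values if isinstance(t, Trajectory) else np.asarray(t, float) for t in group_a])
    B = np.vstack([t.values if isinstance(t, Trajectory) else np.asarray(t, float) for t in group_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups sampled on different numbers of nodes")
    na, nb = len(A), len(B)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 trajectories per group")
    Q = A.shape[1]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df_node = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        df = float(np.mean(df_node))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_curve = (ma - mb) / se
    if not np.all(np.isfinite(t_curve)):
        raise ValueError("zero within-group variance at some node")

    residuals = np.vstack([A - ma, B - mb])
    fwhm = estimate_fwhm(residuals)
    tails = 2 if two_tailed else 1
    t_crit = rft_critical_t(alpha, df, Q, fwhm, tails=tails)
    stat = np.abs(t_curve) if two_tailed else t_curve
    clusters = _suprathreshold_clusters(stat, t_crit)
    return SPMResult(
        t_curve=t_curve,
        df=df,
        fwhm_est=fwhm,
        t_critical=t_crit,
        clusters=clusters,
        two_tailed=two_tailed,
    )


# ---------------------------------------------------------------------------
# I/O: long-format CSV in, JSON + plot-ready CSV out
# ---------------------------------------------------------------------------


def read_trajectories_csv(path, parameter: str, zone: str | None = None) -> dict:
    """Read long-format trajectories (subject, group, time_pct, parameter,
    [zone,] value) and return {group: [Trajectory, ...]}."""
    frame = pd.read_csv(path)
    frame = frame[frame["parameter"] == parameter]
    if zone is not None and "zone" in frame.columns:
        frame = frame[frame["zone"] == zone]
    if frame.empty:
        raise ValueError(f"no rows for parameter {parameter!r}" + (f", zone {zone!r}" if zone else ""))
    groups = {}
    for (grp, _subj), sub in frame.groupby(["group", "subject"], sort=True):
        sub = sub.sort_values("time_pct")
        groups.setdefault(grp, []).append(Trajectory(sub["value"].to_numpy(), sub["time_pct"].to_numpy()))
    return groups


def write_result(result: SPMResult, json_path, curve_csv_path=None) -> None:
    payload = {
        "df": result.df,
        "fwhm_est": result.fwhm_est,
        "t_critical": result.t_critical,
        "max_abs_t": result.max_abs_t,
        "significant": result.significant,
        "two_tailed": result.two_tailed,
        "clusters": [[int(a), int(b)] for a, b in result.clusters],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if curve_csv_path is not None:
        pd.DataFrame(
            {
                "node": np.arange(len(result.t_curve)),
                "t": result.t_curve,
                "t_critical": result.t_critical,
            }
        ).to_csv(curve_csv_path, index=False)
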