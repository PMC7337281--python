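"""Partial-identification bounds for treatment effects under outcome attrition.

Two families of interval estimators for the average treatment effect (ATE)
when outcomes are missing not at random:

* Horowitz-Manski worst-case bounds: assumption-free, obtained by filling the
  missing outcomes in each arm with the extremes of the outcome support.
* Lee trimming bounds: under monotone sample selection (assignment can shift
  the attrition probability in only one direction), the observed outcome
  distribution of the less-attrited arm is trimmed by the attrition
  differential q from either tail; the resulting interval identifies the ATE
  for the *never-attriters* — participants observed under either assignment.
  A conditional variant trims within discrete covariate cells and aggregates
  with never-attriter weights, which tightens the interval when attrition is
  selective on those covariates.

Estimators follow the model/results pattern: construct a model from a
:class:`~trialbounds.data.TrialDataset`, call ``fit()`` to obtain a
:class:`BoundsResult` carrying the bounds, bootstrap uncertainty, the outer
confidence interval and the retained (post-trimming) row set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .data import AnalysisConfig, DegenerateDesignError, TrialDataset
from .diagnostics import attrition_rates

__all__ = [
    "OutcomeSupport",
    "BoundsResult",
    "SupportError",
    "ConditioningInfeasibleError",
    "BootstrapInstabilityError",
    "trimmed_mean",
    "lee_interval",
    "HorowitzManskiBounds",
    "LeeBounds",
    "ConditionalLeeBounds",
    "horowitz_manski_bounds",
    "lee_bounds",
    "conditional_lee_bounds",
    "bounds_ci",
]

_EPS = 1e-12


class SupportError(ValueError):
    """An observed outcome lies outside the declared support."""


class ConditioningInfeasibleError(ValueError):
    """A conditioning cell lacks observed outcomes in one arm."""


class BootstrapInstabilityError(RuntimeError):
    """Too many bootstrap replicates were degenerate to report uncertainty."""


@dataclass(frozen=True)
class OutcomeSupport:
    """Logical range [y_min, y_max] of the outcome scale (e.g. 0..96 for AQ-Total)."""

    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.y_min < self.y_max:
            raise ValueError("y_min must be strictly below y_max")


# ---------------------------------------------------------------------------
# Trimmed mean (the trimming primitive)


def trimmed_mean(
    values: Sequence[float], p: float, tail: str, mode: str = "fractional"
) -> float:
    """Mean after removing probability mass ``p`` from one tail.

    Each of the n observations carries mass 1/n.  In ``fractional`` mode the
    order statistic straddling the p-quantile keeps the fractional remainder
    of its mass, so the estimator matches the population trimming formula and
    is invariant to row order even under ties.  In ``integer`` mode
    ``ceil(p*n)`` whole observations are removed, replicating implementations
    that round.

    ``p = 0`` returns the plain mean.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("values must be non-empty")
    if not 0 <= p < 1:
        raise ValueError("trim fraction p must lie in [0, 1)")
    if tail not in ("lower", "upper"):
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    if p == 0:
        return float(v.mean())
    if tail == "upper":
        v = v[::-1]
    m = p * n
    r = int(np.floor(m + _EPS))
    frac = m - r
    if frac < _EPS:
        frac = 0.0
    if mode == "fractional":
        if r >= n:
            raise ValueError("trim fraction removes the whole sample")
        w = np.ones(n)
        w[:r] = 0.0
        if frac > 0:
            w[r] = 1.0 - frac
        return float(np.dot(w, v) / w.sum())
    if mode == "integer":
        k = r if frac == 0.0 else r + 1
        if k >= n:
            raise ValueError("integer trim removes the whole sample")
        return float(v[k:].mean())
    raise ValueError(f"unknown trim mode: {mode!r}")


def _retained_value_band(values: np.ndarray, p: float) -> tuple[float, float]:
    """Value band [lo, hi] of observations surviving both tail trims of mass p."""
    v = np.sort(values)
    n = v.size
    m = p * n
    r = int(np.floor(m + _EPS))
    lo_idx = min(r, n - 1)
    hi_idx = max(n - 1 - r, 0)
    if lo_idx > hi_idx:
        return (np.inf, -np.inf)
    return (float(v[lo_idx]), float(v[hi_idx]))


def lee_interval(
    trimmed_arm_values: Sequence[float],
    other_arm_mean: float,
    trim_share: float,
    trimmed_arm: str,
    mode: str = "fractional",
) -> tuple[float, float]:
    """Lee bound candidates for a given trim share, sorted as (lower, upper).

    One candidate differences the lower-tail-trimmed mean of the trimmed arm
    against the untrimmed arm's mean, the other the upper-tail-trimmed mean;
    the signed difference is always treated-minus-control.  Exposed separately
    so the width-vs-trim-share behaviour can be studied directly.
    """
    tm_lo = trimmed_mean(trimmed_arm_values, trim_share, "lower", mode)
    tm_hi = trimmed_mean(trimmed_arm_values, trim_share, "upper", mode)
    if trimmed_arm == "control":
        cands = (other_arm_mean - tm_lo, other_arm_mean - tm_hi)
    elif trimmed_arm == "treated":
        cands = (tm_lo - other_arm_mean, tm_hi - other_arm_mean)
    else:
        raise ValueError(f"trimmed_arm must be 'treated' or 'control', got {trimmed_arm!r}")
    return (min(cands), max(cands))


# ---------------------------------------------------------------------------
# Results object


@dataclass(frozen=True)
class BoundsResult:
    """Interval estimate of the ATE with bootstrap uncertainty.

    ``[lower, upper]`` is the identified set for the never-attriter ATE (for
    trimming methods) or for the full-sample ATE (worst-case method);
    ``ci_outer`` extends each bound outward by its own sampling uncertainty so
    it covers the entire identified set at ``ci_level``.
    """

    lower: float
    upper: float
    method: str
    trim_share: float
    trimmed_arm: str | None
    ci_level: float = 0.95
    se_lower: float | None = None
    se_upper: float | None = None
    ci_outer: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_dropped_replicates: int = 0
    cells: pd.DataFrame | None = None
    trimmed_rows: tuple | None = field(default=None, repr=False)
    fallback_to_unconditional: bool = False
    extras: dict = field(default_factory=dict, repr=False)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def ci_width(self) -> float | None:
        if self.ci_outer is None:
            return None
        return self.ci_outer[1] - self.ci_outer[0]

    def summary(self) -> str:
        lines = [
            f"{'Treatment-effect bounds':^60}",
            "=" * 60,
            f"Method:              {self.method}",
            f"Trim share (q):      {self.trim_share:.4f}"
            + (f"   trimmed arm: {self.trimmed_arm}" if self.trimmed_arm else ""),
            "-" * 60,
            f"Lower bound:         {self.lower:10.4f}"
            + (f"   (se {self.se_lower:.4f})" if self.se_lower is not None else ""),
            f"Upper bound:         {self.upper:10.4f}"
            + (f"   (se {self.se_upper:.4f})" if self.se_upper is not None else ""),
            f"Interval width:      {self.width:10.4f}",
        ]
        if self.ci_outer is not None:
            lines += [
                f"{self.ci_level:.0%} outer CI:        "
                f"[{self.ci_outer[0]:.4f}, {self.ci_outer[1]:.4f}]"
                f"   (width {self.ci_width:.4f})",
                f"Bootstrap reps:      {self.n_bootstrap}"
                + (
                    f"   ({self.n_dropped_replicates} degenerate, dropped)"
                    if self.n_dropped_replicates
                    else ""
                ),
            ]
        if self.fallback_to_unconditional:
            lines.append("Note: fell back to unconditional trimming (no covariate selected).")
        if self.cells is not None:
            lines += ["-" * 60, "Per-cell detail:", self.cells.to_string(index=False)]
        lines.append("=" * 60)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "lower": self.lower,
            "upper": self.upper,
            "width": self.width,
            "trim_share": self.trim_share,
            "trimmed_arm": self.trimmed_arm,
            "ci_level": self.ci_level,
            "se_lower": self.se_lower,
            "se_upper": self.se_upper,
            "ci_outer": list(self.ci_outer) if self.ci_outer else None,
            "n_bootstrap": self.n_bootstrap,
            "n_dropped_replicates": self.n_dropped_replicates,
            "fallback_to_unconditional": self.fallback_to_unconditional,
        }
        if self.cells is not None:
            d["cells"] = self.cells.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# Model classes


class _BoundsModel:
    """Shared point-estimate + within-arm bootstrap machinery."""

    method: str = ""

    def __init__(self, ds: TrialDataset):
        self.data = ds
        self._y = ds.y
        self._t = ds.t
        self._s = ds.s

    # subclasses implement the point estimator on a position subset
    def _point(self, pos: np.ndarray) -> dict:
        raise NotImplementedError

    def _full_positions(self) -> np.ndarray:
        return np.arange(self.data.n)

    def point(self) -> BoundsResult:
        """Bounds on the full sample, without bootstrap uncertainty."""
        info = self._point(self._full_positions())
        return BoundsResult(method=self.method, **info)

    def fit(
        self,
        config: AnalysisConfig | None = None,
        n_bootstrap: int | None = None,
        seed: int | None = None,
        ci_level: float | None = None,
        ci_method: str = "outer",
    ) -> BoundsResult:
        """Estimate bounds and their bootstrap uncertainty.

        The bootstrap resamples participants with replacement within each arm
        and recomputes the entire procedure (attrition rates, trim shares and
        directions, cell bounds) on every replicate.  Replicates on which the
        estimator is degenerate (e.g. an arm loses all observed outcomes) are
        dropped and counted; more than 20% dropped raises
        :class:`BootstrapInstabilityError`.

        ``ci_method='outer'`` extends each bound outward by z * se;
        ``'imbens-manski'`` uses the uniformity-corrected critical value for
        coverage of the parameter rather than of the whole identified set.
        """
        cfg = config or AnalysisConfig()
        B = n_bootstrap if n_bootstrap is not None else cfg.n_bootstrap
        level = ci_level if ci_level is not None else cfg.ci_level
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)

        info = self._point(self._full_positions())
        lower, upper = info["lower"], info["upper"]

        treated_pos = np.flatnonzero(self._t == 1)
        control_pos = np.flatnonzero(self._t == 0)
        lows, ups = [], []
        dropped = 0
        for _ in range(B):
            pos = np.concatenate(
                [
                    rng.choice(treated_pos, size=treated_pos.size, replace=True),
                    rng.choice(control_pos, size=control_pos.size, replace=True),
                ]
            )
            try:
                rep = self._point(pos, detail=False)
            except (DegenerateDesignError, ConditioningInfeasibleError, ValueError):
                dropped += 1
                continue
            lows.append(rep["lower"])
            ups.append(rep["upper"])
        if dropped > 0.2 * B:
            raise BootstrapInstabilityError(
                f"{dropped}/{B} bootstrap replicates degenerate; bounds unstable"
            )
        se_lo = float(np.std(lows, ddof=1)) if len(lows) > 1 else 0.0
        se_up = float(np.std(ups, ddof=1)) if len(ups) > 1 else 0.0
        crit = _critical_value(ci_method, level, lower, upper, se_lo, se_up)
        ci = (lower - crit * se_lo, upper + crit * se_up)
        return BoundsResult(
            method=self.method,
            ci_level=level,
            se_lower=se_lo,
            se_upper=se_up,
            ci_outer=ci,
            n_bootstrap=len(lows),
            n_dropped_replicates=dropped,
            **info,
        )


def _critical_value(
    ci_method: str, level: float, lower: float, upper: float, se_lo: float, se_up: float
) -> float:
    if ci_method == "outer":
        return float(stats.norm.ppf(1 - (1 - level) / 2))
    if ci_method == "imbens-manski":
        se_max = max(se_lo, se_up)
        if se_max == 0:
            return float(stats.norm.ppf(level))
        delta = (upper - lower) / se_max

        def f(c: float) -> float:
            return stats.norm.cdf(c + delta) - stats.norm.cdf(-c) - level

        return float(brentq(f, 0.0, 10.0))
    raise ValueError(f"unknown ci_method: {ci_method!r}")


class HorowitzManskiBounds(_BoundsModel):
    """Assumption-free worst-case bounds on the ATE.

    Missing outcomes in each arm are replaced by the best- and worst-case
    values of the declared outcome support; the two fill-in patterns that
    minimise and maximise the treated-minus-control mean difference give the
    bounds.  No trimming occurs and no selection assumption is used.
    """

    method = "horowitz-manski"

    def __init__(self, ds: TrialDataset, support: OutcomeSupport):
        super().__init__(ds)
        obs = ds.y[ds.s == 1]
        if obs.size and (obs.min() < support.y_min or obs.max() > support.y_max):
            raise SupportError(
                f"observed outcomes in [{obs.min()}, {obs.max()}] exceed support "
                f"[{support.y_min}, {support.y_max}]"
            )
        self.support = support

    def _point(self, pos: np.ndarray, detail: bool = True) -> dict:
        y, t, s = self._y[pos], self._t[pos], self._s[pos]
        lo, hi = self.support.y_min, self.support.y_max
        out = {}
        for name, fill_t, fill_c in (("lower", lo, hi), ("upper", hi, lo)):
            yt = np.where(s == 1, y, fill_t)[t == 1]
            yc = np.where(s == 1, y, fill_c)[t == 0]
            if yt.size == 0 or yc.size == 0:
                raise DegenerateDesignError("empty arm in replicate")
            out[name] = float(yt.mean() - yc.mean())
        res = {"lower": out["lower"], "upper": out["upper"], "trim_share": 0.0,
               "trimmed_arm": None}
        if detail:
            res["trimmed_rows"] = tuple(self.data.frame.index)
        return res


def _arm_rates(t: np.ndarray, s: np.ndarray) -> tuple[float, float, float, str]:
    """(q_treated, q_control, trim_share, trimmed_arm) from indicator arrays."""
    n1 = (t == 1).sum()
    n0 = (t == 0).sum()
    o1 = ((t == 1) & (s == 1)).sum()
    o0 = ((t == 0) & (s == 1)).sum()
    if n1 == 0 or n0 == 0 or o1 == 0 or o0 == 0:
        raise DegenerateDesignError("an arm has no observed outcomes")
    q1, q0 = o1 / n1, o0 / n0
    q = (max(q0, q1) - min(q0, q1)) / max(q0, q1)
    return q1, q0, q, ("treated" if q1 > q0 else "control")


class LeeBounds(_BoundsModel):
    """Trimming bounds for the never-attriter ATE under monotone selection.

    The less-attrited arm's observed outcome distribution is trimmed by the
    attrition differential q from the lower and the upper tail in turn; each
    trimmed mean is differenced against the other arm's observed mean and the
    two candidates are sorted into (lower, upper).  Computing both candidates
    and sorting keeps the estimator free of any sign convention for the
    outcome (here, symptom scales improve downward).
    """

    method = "lee"

    def __init__(self, ds: TrialDataset, trim_mode: str = "fractional"):
        super().__init__(ds)
        if trim_mode not in ("fractional", "integer"):
            raise ValueError(f"unknown trim mode: {trim_mode!r}")
        self.trim_mode = trim_mode
        attrition_rates(ds)  # validate up front

    def _point(self, pos: np.ndarray, detail: bool = True) -> dict:
        y, t, s = self._y[pos], self._t[pos], self._s[pos]
        _, _, q, trimmed_arm = _arm_rates(t, s)
        trim_code = 1 if trimmed_arm == "treated" else 0
        v_trim = y[(t == trim_code) & (s == 1)]
        v_other = y[(t == 1 - trim_code) & (s == 1)]
        lower, upper = lee_interval(v_trim, float(v_other.mean()), q, trimmed_arm,
                                    self.trim_mode)
        res = {"lower": lower, "upper": upper, "trim_share": q,
               "trimmed_arm": trimmed_arm}
        if detail:
            res["trimmed_rows"] = self._retained_rows(pos, q, trim_code)
        return res

    def _retained_rows(self, pos: np.ndarray, q: float, trim_code: int) -> tuple:
        """Rows surviving both tail trims plus the untrimmed arm's observed rows."""
        y, t, s = self._y[pos], self._t[pos], self._s[pos]
        idx = self.data.frame.index.to_numpy()[pos]
        keep_other = (t == 1 - trim_code) & (s == 1)
        in_trim = (t == trim_code) & (s == 1)
        lo, hi = _retained_value_band(y[in_trim], q)
        keep_trim = in_trim & (y >= lo) & (y <= hi)
        return tuple(idx[keep_other | keep_trim])


class ConditionalLeeBounds(_BoundsModel):
    """Cell-wise Lee bounds, aggregated over never-attriter cell weights.

    Trimming is performed separately within each discrete cell (each with its
    own trim share and direction), and the per-cell bounds are averaged with
    weights proportional to each cell's share of observed participants in the
    globally untrimmed (more-attrited) arm — the reference population of
    never-attriters.  Cells below the minimum per-arm observed count are
    pooled into an ``(other)`` cell.
    """

    method = "lee-conditional"

    def __init__(
        self,
        ds: TrialDataset,
        cells: str | Sequence | pd.Series,
        trim_mode: str = "fractional",
        min_cell_per_arm: int = 1,
        cell_rules: dict | None = None,
    ):
        super().__init__(ds)
        self.trim_mode = trim_mode
        self.min_cell_per_arm = int(min_cell_per_arm)
        self.cell_rules = cell_rules or {}
        if isinstance(cells, str):
            labels = ds.frame[cells].to_numpy()
        elif isinstance(cells, pd.Series):
            labels = cells.reindex(ds.frame.index).to_numpy()
        else:
            labels = np.asarray(cells)
            if labels.shape[0] != ds.n:
                raise ValueError("cell assignment length must match the sample")
        if pd.isna(labels).any():
            raise ValueError("every row must be assigned to exactly one cell")
        self._labels = self._merge_small_cells(labels.astype(object))
        attrition_rates(ds)

    def _merge_small_cells(self, labels: np.ndarray) -> np.ndarray:
        t, s = self._t, self._s
        out = labels.copy()
        counts = {}
        for c in pd.unique(out):
            m = out == c
            counts[c] = (
                int((m & (t == 1) & (s == 1)).sum()),
                int((m & (t == 0) & (s == 1)).sum()),
            )
        small = [c for c, (a, b) in counts.items()
                 if a < self.min_cell_per_arm or b < self.min_cell_per_arm]
        if not small:
            return out
        big = [c for c in counts if c not in small]
        out[np.isin(out, small)] = "(other)"
        a = int(((out == "(other)") & (t == 1) & (s == 1)).sum())
        b = int(((out == "(other)") & (t == 0) & (s == 1)).sum())
        if a == 0 or b == 0:
            raise ConditioningInfeasibleError(
                "cell '(other)' has no observed outcomes in one arm after merging"
            )
        if (a < self.min_cell_per_arm or b < self.min_cell_per_arm) and big:
            # pooled remainder still too small: absorb it into the smallest
            # surviving cell so the estimator stays defined
            smallest = min(big, key=lambda c: sum(counts[c]))
            out[out == "(other)"] = smallest
        return out

    def _point(self, pos: np.ndarray, detail: bool = True) -> dict:
        y, t, s = self._y[pos], self._t[pos], self._s[pos]
        labels = self._labels[pos]
        _, _, q_global, global_trimmed = _arm_rates(t, s)
        untrimmed_code = 0 if global_trimmed == "treated" else 1
        ref = (t == untrimmed_code) & (s == 1)  # never-attriter reference arm
        n_ref = ref.sum()

        cell_ids = list(pd.unique(labels))
        rows: list[dict] = []
        lower = upper = 0.0
        retained: list = []
        for cid in cell_ids:
            m = labels == cid
            tc, sc, yc = t[m], s[m], y[m]
            try:
                _, _, q_c, arm_c = _arm_rates(tc, sc)
            except DegenerateDesignError as exc:
                raise ConditioningInfeasibleError(
                    f"cell {cid!r} has no observed outcomes in one arm"
                ) from exc
            code_c = 1 if arm_c == "treated" else 0
            v_trim = yc[(tc == code_c) & (sc == 1)]
            v_other = yc[(tc == 1 - code_c) & (sc == 1)]
            lo_c, up_c = lee_interval(v_trim, float(v_other.mean()), q_c, arm_c,
                                      self.trim_mode)
            w = float((m & ref).sum() / n_ref)
            lower += w * lo_c
            upper += w * up_c
            if detail:
                rows.append(
                    {
                        "cell": cid,
                        "rule": self.cell_rules.get(cid, str(cid)),
                        "n_treated": int((m & (t == 1)).sum()),
                        "n_control": int((m & (t == 0)).sum()),
                        "obs_treated": int((m & (t == 1) & (s == 1)).sum()),
                        "obs_control": int((m & (t == 0) & (s == 1)).sum()),
                        "trim_share": q_c,
                        "trimmed_arm": arm_c,
                        "weight": w,
                        "lower": lo_c,
                        "upper": up_c,
                    }
                )
                idx = self.data.frame.index.to_numpy()[pos][m]
                keep_other = (tc == 1 - code_c) & (sc == 1)
                in_trim = (tc == code_c) & (sc == 1)
                lo_v, hi_v = _retained_value_band(yc[in_trim], q_c)
                keep_trim = in_trim & (yc >= lo_v) & (yc <= hi_v)
                retained.extend(idx[keep_other | keep_trim].tolist())

        res = {"lower": lower, "upper": upper, "trim_share": q_global,
               "trimmed_arm": global_trimmed}
        if detail:
            res["cells"] = pd.DataFrame(rows)
            res["trimmed_rows"] = tuple(retained)
        return res


# ---------------------------------------------------------------------------
# Functional wrappers


def horowitz_manski_bounds(ds: TrialDataset, support: OutcomeSupport) -> BoundsResult:
    """Worst-case bounds without uncertainty; see :class:`HorowitzManskiBounds`."""
    return HorowitzManskiBounds(ds, support).point()


def lee_bounds(ds: TrialDataset, trim_mode: str = "fractional") -> BoundsResult:
    """Unconditional trimming bounds without uncertainty; see :class:`LeeBounds`."""
    return LeeBounds(ds, trim_mode).point()


def conditional_lee_bounds(
    ds: TrialDataset,
    cells: str | Sequence | pd.Series,
    trim_mode: str = "fractional",
    min_cell_per_arm: int = 1,
) -> BoundsResult:
    """Cell-wise trimming bounds without uncertainty; see :class:`ConditionalLeeBounds`."""
    return ConditionalLeeBounds(ds, cells, trim_mode, min_cell_per_arm).point()


def bounds_ci(
    ds: TrialDataset,
    method: str = "lee",
    config: AnalysisConfig | None = None,
    support: OutcomeSupport | None = None,
    cells: str | Sequence | pd.Series | None = None,
    ci_method: str = "outer",
) -> BoundsResult:
    """Bounds with bootstrap standard errors and the outer confidence interval.

    Dispatches on ``method`` in {'hm', 'lee', 'lee-cond'}; the random-forest
    pipeline lives in :mod:`trialbounds.rflb`.
    """
    cfg = config or AnalysisConfig()
    if method in ("hm", "horowitz-manski"):
        if support is None:
            raise ValueError("horowitz-manski bounds require an OutcomeSupport")
        model: _BoundsModel = HorowitzManskiBounds(ds, support)
    elif method == "lee":
        model = LeeBounds(ds, cfg.trim_mode)
    elif method in ("lee-cond", "lee-conditional"):
        if cells is None:
            raise ValueError("conditional bounds require a cell assignment")
        model = ConditionalLeeBounds(ds, cells, cfg.trim_mode)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return model.fit(config=cfg, ci_method=ci_method)
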