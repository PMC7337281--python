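"""Random-forest Lee bounds (RFLB).

Tightens Lee trimming bounds by conditioning on the covariates — including
continuous ones — that actually predict attrition.  Four steps:

1. fit a random-forest classifier of the attrition indicator on treatment,
   the baseline covariates and an injected pure-noise *random benchmark*
   column;
2. rank covariates by cross-validated permutation importance, normalized so
   the top feature scores 1; only covariates strictly more important than the
   benchmark are candidates;
3. confirm each candidate's treatment-interaction importance the same way
   (selective attrition alone is necessary but not sufficient — the
   attrition-treatment covariation must itself depend on the covariate for
   conditioning to tighten the bounds);
4. discretize the confirmed covariates with a small decision tree and run
   cell-wise conditional Lee bounds on its leaves.

When nothing clears the benchmark the pipeline falls back, explicitly, to the
unconditional Lee bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .bounds import BoundsResult, ConditionalLeeBounds, LeeBounds
from .data import AnalysisConfig, TrialDataset

__all__ = [
    "ImportanceReport",
    "ConditioningScheme",
    "NoAttritionError",
    "attrition_importance",
    "build_conditioning_scheme",
    "RandomForestLeeBounds",
    "rflb_bounds",
    "export_importance_graph",
]

_BENCHMARK = "__benchmark__"


class NoAttritionError(ValueError):
    """Attrition is absent (or total); the importance screen is undefined."""


# ---------------------------------------------------------------------------
# Report / scheme containers


@dataclass(frozen=True)
class ImportanceReport:
    """Covariate importances for attrition, relative to a random benchmark.

    Importances are permutation importances (held-out AUC drop) averaged over
    cross-validation folds and normalized so the most important feature scores
    1.  ``selected`` holds covariates strictly above the benchmark;
    ``interaction_selected`` the covariates whose treatment-interaction
    feature clears the interaction benchmark in a second forest.
    """

    importances: dict
    benchmark_importance: float
    selected: tuple[str, ...]
    interaction_importances: dict
    interaction_benchmark_importance: float
    interaction_selected: tuple[str, ...]
    treatment_importance: float
    seed: int
    cv_folds: int
    selection_rule: str = "both"

    @property
    def conditioning_set(self) -> tuple[str, ...]:
        """Covariates used for conditioning under the active selection rule."""
        if self.selection_rule == "main-only":
            return self.selected
        return tuple(c for c in self.selected if c in self.interaction_selected)

    def to_dict(self) -> dict:
        return {
            "importances": self.importances,
            "benchmark_importance": self.benchmark_importance,
            "treatment_importance": self.treatment_importance,
            "selected": list(self.selected),
            "interaction_importances": self.interaction_importances,
            "interaction_benchmark_importance": self.interaction_benchmark_importance,
            "interaction_selected": list(self.interaction_selected),
            "conditioning_set": list(self.conditioning_set),
            "seed": self.seed,
            "cv_folds": self.cv_folds,
            "selection_rule": self.selection_rule,
        }


@dataclass(frozen=True)
class ConditioningScheme:
    """Decision-tree-derived discrete cells used for cell-wise trimming."""

    splits: tuple[dict, ...]
    cells: pd.DataFrame  # id, rule, per-arm assigned and observed counts
    assignment: np.ndarray = field(repr=False)  # row -> cell id
    features: tuple[str, ...] = ()
    _tree: DecisionTreeClassifier | None = field(default=None, repr=False, compare=False)
    _encoder_columns: tuple[str, ...] = field(default=(), repr=False)
    _leaf_to_cell: dict = field(default_factory=dict, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def assign(self, covariate_frame: pd.DataFrame) -> np.ndarray:
        """Cell labels for new rows with the same covariate columns."""
        if self._tree is None:
            if self.n_cells == 1:
                only = self.cells["cell"].iloc[0]
                return np.full(len(covariate_frame), only, dtype=object)
            raise ValueError("scheme carries no fitted tree")
        X = _encode(covariate_frame[list(self.features)])
        X = X.reindex(columns=list(self._encoder_columns), fill_value=0.0)
        leaves = self._tree.apply(X.to_numpy(dtype=float))
        return np.array([self._leaf_to_cell[l] for l in leaves], dtype=object)

    def rules_text(self) -> str:
        lines = [f"Conditioning tree on {', '.join(self.features)}:"]
        for _, row in self.cells.iterrows():
            lines.append(
                f"  cell {row['cell']}: {row['rule']}  "
                f"[treated {row['obs_treated']}/{row['n_treated']} observed, "
                f"control {row['obs_control']}/{row['n_control']}]"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Feature encoding and grouped permutation importance


def _encode(X: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categoricals; column names keep the source covariate prefix."""
    return pd.get_dummies(X, prefix_sep="::", dtype=float)


def _column_groups(encoded: pd.DataFrame, covariates: Sequence[str]) -> dict:
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        cols = [c for c in encoded.columns if c == cov or c.startswith(f"{cov}::")]
        if cols:
            groups[cov] = cols
    return groups


def _stratified_permutation(
    rng: np.random.Generator, n: int, strata: np.ndarray | None
) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    out = np.arange(n)
    for level in np.unique(strata):
        idx = np.flatnonzero(strata == level)
        out[idx] = idx[rng.permutation(idx.size)]
    return out


def _grouped_permutation_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: dict,
    settings,
    seed: int,
    strata: np.ndarray | None = None,
) -> dict:
    """Cross-validated permutation importance per feature group.

    Every row is predicted by the fold model not trained on it; the baseline
    score is the Brier score of the pooled out-of-fold probabilities.  For
    each group, its columns are jointly permuted over the *full* sample (the
    same permutation across folds, repeated ``n_permutations`` times) and the
    pooled score recomputed; the importance is the mean score drop.  Pooling
    before scoring and permuting full-length keeps the estimate usable on
    trial-sized samples, where per-fold scores are dominated by noise.  When
    ``strata`` is given, permutations are drawn within each stratum, leaving
    the stratum structure of the feature intact (used to score interaction
    features within arms).
    Permuting all one-hot columns of a covariate jointly scores the covariate
    as a unit; permutation (rather than impurity) importance avoids the bias
    toward continuous features that would rig the benchmark comparison.
    """
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=settings.cv_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    col_idx = {g: [X.columns.get_loc(c) for c in cols] for g, cols in groups.items()}
    perms = [
        _stratified_permutation(rng, n, strata)
        for _ in range(settings.n_permutations)
    ]
    oof = np.zeros(n)
    perm_oof = {g: np.zeros((settings.n_permutations, n)) for g in groups}
    group_names = list(groups)
    for train, test in skf.split(Xv, y):
        forest = RandomForestClassifier(
            n_estimators=settings.n_trees,
            max_features=settings.max_features,
            min_samples_leaf=settings.min_leaf,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(Xv[train], y[train])
        # one batched predict per fold: baseline block plus every
        # (group, permutation) block stacked
        blocks = [Xv[test]]
        for g in group_names:
            idx = col_idx[g]
            for perm in perms:
                Xp = Xv[test].copy()
                Xp[:, idx] = Xv[perm][:, idx][test]
                blocks.append(Xp)
        proba = forest.predict_proba(np.vstack(blocks))[:, 1]
        m = test.size
        oof[test] = proba[:m]
        k = 1
        for g in group_names:
            for r in range(settings.n_permutations):
                perm_oof[g][r, test] = proba[k * m:(k + 1) * m]
                k += 1

    def brier(p: np.ndarray) -> float:
        return float(np.mean((p - y) ** 2))

    base = brier(oof)
    return {
        g: float(np.mean([brier(perm_oof[g][r]) for r in range(settings.n_permutations)]))
        - base
        for g in groups
    }


def _normalize(raw: dict) -> dict:
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    top = max(clipped.values(), default=0.0)
    if top <= 0:
        return {k: 0.0 for k in clipped}
    return {k: v / top for k, v in clipped.items()}


# ---------------------------------------------------------------------------
# Step 1-2: importance screen


def attrition_importance(
    ds: TrialDataset,
    config: AnalysisConfig | None = None,
    selection_rule: str = "both",
) -> ImportanceReport:
    """Forest-based attrition importances with the random-benchmark screen.

    Fits one forest of the attrition indicator on {treatment, covariates,
    benchmark} and a second adding explicit treatment-interaction features
    (products with continuous covariates, treatment x level indicators for
    categoricals, and treatment x benchmark as the interaction benchmark).
    A covariate is *selected* when its normalized importance strictly exceeds
    the benchmark's; under ``selection_rule='both'`` (default) it enters the
    conditioning set only if its interaction feature clears the interaction
    benchmark as well.
    """
    cfg = config or AnalysisConfig()
    if not ds.covariates:
        raise ValueError("at least one covariate is required")
    s = ds.s
    if s.min() == s.max():
        raise NoAttritionError("attrition indicator is constant; nothing to screen")
    if selection_rule not in ("both", "main-only"):
        raise ValueError(f"unknown selection_rule: {selection_rule!r}")

    ss = np.random.SeedSequence(cfg.seed)
    k_bench, k_main, k_inter = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

    X = _encode(ds.covariate_frame())
    if X.isna().any().any():
        raise ValueError("missing covariate values; apply a missing-data policy first")
    n_probes = cfg.rf_settings.benchmark_probes
    probe_rng = np.random.default_rng(k_bench)
    probes = {f"{_BENCHMARK}{i}": probe_rng.uniform(size=ds.n) for i in range(n_probes)}
    probe_names = list(probes)
    target = 1 - s  # predict attrition

    # --- main-effect forest
    X1 = X.copy()
    X1["treatment"] = ds.t.astype(float)
    for name, vals in probes.items():
        X1[name] = vals
    groups1 = _column_groups(X1, list(ds.covariates))
    groups1["treatment"] = ["treatment"]
    for name in probe_names:
        groups1[name] = [name]
    raw1 = _grouped_permutation_importance(X1, target, groups1, cfg.rf_settings, k_main)
    bench_raw = max(raw1[p] for p in probe_names)
    norm1 = _normalize(
        {k: v for k, v in raw1.items() if k not in probe_names} | {_BENCHMARK: bench_raw}
    )
    bench_imp = norm1.pop(_BENCHMARK)
    treat_imp = norm1.pop("treatment")
    selected = tuple(c for c in ds.covariates if norm1.get(c, 0.0) > bench_imp)

    # --- interaction forest: treatment plus product features only, so a
    # product's importance measures the covariate's signal specifically where
    # treatment acts, instead of being masked by the main effects
    X2 = pd.DataFrame({"treatment": ds.t.astype(float)}, index=X.index)
    inter_groups: dict[str, list[str]] = {}
    for cov in ds.covariates:
        cols = _column_groups(X, [cov]).get(cov, [])
        inter_cols = []
        for c in cols:
            name = f"treatment*{c}"
            X2[name] = X2["treatment"] * X[c]
            inter_cols.append(name)
        if inter_cols:
            inter_groups[f"treatment*{cov}"] = inter_cols
    for name, vals in probes.items():
        X2[f"treatment*{name}"] = X2["treatment"] * vals
    groups2 = dict(inter_groups)
    groups2["treatment"] = ["treatment"]
    for name in probe_names:
        groups2[f"treatment*{name}"] = [f"treatment*{name}"]
    raw2 = _grouped_permutation_importance(
        X2, target, groups2, cfg.rf_settings, k_inter, strata=ds.t
    )
    inter_bench_raw = max(raw2[f"treatment*{p}"] for p in probe_names)
    norm2 = _normalize(
        {k: v for k, v in raw2.items() if not k.startswith(f"treatment*{_BENCHMARK}")}
        | {f"treatment*{_BENCHMARK}": inter_bench_raw}
    )
    inter_bench = norm2[f"treatment*{_BENCHMARK}"]
    inter_imps = {cov: norm2.get(f"treatment*{cov}", 0.0) for cov in ds.covariates}
    inter_selected = tuple(c for c in ds.covariates if inter_imps[c] > inter_bench)

    return ImportanceReport(
        importances={c: norm1.get(c, 0.0) for c in ds.covariates},
        benchmark_importance=bench_imp,
        selected=selected,
        interaction_importances=inter_imps,
        interaction_benchmark_importance=inter_bench,
        interaction_selected=inter_selected,
        treatment_importance=treat_imp,
        seed=cfg.seed,
        cv_folds=cfg.rf_settings.cv_folds,
        selection_rule=selection_rule,
    )


# ---------------------------------------------------------------------------
# Step 3-4: conditioning tree


def _leaf_rules(tree: DecisionTreeClassifier, columns: Sequence[str]) -> dict:
    """Human-readable split-path rule per leaf node id."""
    t = tree.tree_
    rules: dict[int, str] = {}

    def walk(node: int, conds: list[str]) -> None:
        if t.children_left[node] == -1:
            rules[node] = " & ".join(conds) if conds else "(all)"
            return
        name = columns[t.feature[node]]
        thr = t.threshold[node]
        walk(t.children_left[node], conds + [f"{name} <= {thr:.4g}"])
        walk(t.children_right[node], conds + [f"{name} > {thr:.4g}"])

    walk(0, [])
    return rules


def _tree_distance(tree: DecisionTreeClassifier, a: int, b: int) -> int:
    """Path distance between two nodes (merging prefers the nearest sibling)."""
    t = tree.tree_
    parent = {}
    for node in range(t.node_count):
        for child in (t.children_left[node], t.children_right[node]):
            if child != -1:
                parent[child] = node

    def ancestors(n: int) -> list[int]:
        out = [n]
        while n in parent:
            n = parent[n]
            out.append(n)
        return out

    pa, pb = ancestors(a), ancestors(b)
    common = set(pa) & set(pb)
    return min(pa.index(c) + pb.index(c) for c in common)


def build_conditioning_scheme(
    ds: TrialDataset,
    report: ImportanceReport,
    config: AnalysisConfig | None = None,
) -> ConditioningScheme:
    """Discretize the selected covariates into cells with a small decision tree.

    A depth-limited classification tree predicts the attrition indicator from
    the conditioning-set covariates only (treatment never splits); its leaves
    become trimming cells.  Leaves below the configured minimum per-arm
    observed count are merged into the nearest leaf by tree-path distance, so
    every cell can support its own trimmed means.  Deterministic given the
    config seed.
    """
    cfg = config or AnalysisConfig()
    features = report.conditioning_set
    if not features:
        raise ValueError(
            "empty conditioning set: fall back to unconditional lee_bounds"
        )
    X = _encode(ds.covariate_frame()[list(features)])
    t_arr, s_arr = ds.t, ds.s
    if cfg.tree_settings.max_leaves == 1:
        # no splits possible: one trivial cell covering everyone, so the
        # downstream conditional bounds reduce to the unconditional ones
        cells = pd.DataFrame(
            [{
                "cell": "(all)", "rule": "(all)",
                "n_treated": int((t_arr == 1).sum()),
                "n_control": int((t_arr == 0).sum()),
                "obs_treated": int(((t_arr == 1) & (s_arr == 1)).sum()),
                "obs_control": int(((t_arr == 0) & (s_arr == 1)).sum()),
            }]
        )
        return ConditioningScheme(
            splits=(), cells=cells,
            assignment=np.full(ds.n, "(all)", dtype=object),
            features=tuple(features),
        )
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    tree = DecisionTreeClassifier(
        max_leaf_nodes=cfg.tree_settings.max_leaves,
        min_samples_leaf=max(cfg.tree_settings.min_cell_per_arm, 1),
        random_state=seed,
    )
    tree.fit(X.to_numpy(dtype=float), 1 - ds.s)
    leaves = tree.apply(X.to_numpy(dtype=float))
    rules = _leaf_rules(tree, list(X.columns))

    # merge undersized leaves into their nearest surviving neighbour

    def counts(group: set) -> tuple[int, int]:
        m = np.isin(leaves, list(group))
        return (
            int((m & (t_arr == 1) & (s_arr == 1)).sum()),
            int((m & (t_arr == 0) & (s_arr == 1)).sum()),
        )

    merged: dict[int, set] = {l: {l} for l in np.unique(leaves)}
    min_n = cfg.tree_settings.min_cell_per_arm
    while len(merged) > 1:
        bad = [
            cid
            for cid, grp in merged.items()
            if min(counts(grp)) < min_n
        ]
        if not bad:
            break
        worst = min(bad, key=lambda c: sum(counts(merged[c])))
        others = [c for c in merged if c != worst]
        nearest = min(others, key=lambda c: min(
            _tree_distance(tree, a, b) for a in merged[worst] for b in merged[c]
        ))
        merged[nearest] |= merged.pop(worst)

    leaf_to_cell = {}
    for cid, grp in merged.items():
        for leaf in grp:
            leaf_to_cell[leaf] = cid
    assignment = np.array([leaf_to_cell[l] for l in leaves], dtype=object)

    rows = []
    for cid, grp in merged.items():
        m = np.isin(leaves, list(grp))
        rows.append(
            {
                "cell": cid,
                "rule": " OR ".join(sorted(rules[l] for l in grp)),
                "n_treated": int((m & (t_arr == 1)).sum()),
                "n_control": int((m & (t_arr == 0)).sum()),
                "obs_treated": int((m & (t_arr == 1) & (s_arr == 1)).sum()),
                "obs_control": int((m & (t_arr == 0) & (s_arr == 1)).sum()),
            }
        )
    t_struct = tree.tree_
    splits = tuple(
        {
            "node": int(n),
            "feature": list(X.columns)[t_struct.feature[n]],
            "threshold": float(t_struct.threshold[n]),
            "left": int(t_struct.children_left[n]),
            "right": int(t_struct.children_right[n]),
        }
        for n in range(t_struct.node_count)
        if t_struct.children_left[n] != -1
    )
    return ConditioningScheme(
        splits=splits,
        cells=pd.DataFrame(rows),
        assignment=assignment,
        features=tuple(features),
        _tree=tree,
        _encoder_columns=tuple(X.columns),
        _leaf_to_cell=leaf_to_cell,
    )


# ---------------------------------------------------------------------------
# Full pipeline


class RandomForestLeeBounds:
    """Model object for the full RFLB pipeline on one trial dataset.

    ``fit()`` runs the importance screen, builds the conditioning scheme (or
    falls back to unconditional trimming when nothing clears the benchmark),
    computes cell-wise conditional Lee bounds, and bootstraps the confidence
    interval holding the conditioning scheme fixed while re-estimating all
    trim shares per replicate.
    """

    method = "rflb"

    def __init__(
        self,
        ds: TrialDataset,
        config: AnalysisConfig | None = None,
        selection_rule: str = "both",
    ):
        self.data = ds
        self.config = config or AnalysisConfig()
        self.selection_rule = selection_rule
        self.report_: ImportanceReport | None = None
        self.scheme_: ConditioningScheme | None = None

    def fit(self, n_bootstrap: int | None = None) -> BoundsResult:
        cfg = self.config
        report = attrition_importance(self.data, cfg, self.selection_rule)
        self.report_ = report
        if not report.conditioning_set:
            model: LeeBounds | ConditionalLeeBounds = LeeBounds(self.data, cfg.trim_mode)
            model.method = "rflb"  # type: ignore[misc]
            res = model.fit(config=cfg, n_bootstrap=n_bootstrap)
            return BoundsResult(
                **{
                    **res.__dict__,
                    "fallback_to_unconditional": True,
                    "extras": {"importance_report": report, "conditioning_scheme": None},
                }
            )
        scheme = build_conditioning_scheme(self.data, report, cfg)
        self.scheme_ = scheme
        rules = dict(zip(scheme.cells["cell"], scheme.cells["rule"]))
        model = ConditionalLeeBounds(
            self.data,
            cells=scheme.assignment,
            trim_mode=cfg.trim_mode,
            min_cell_per_arm=1,  # the scheme already enforces cell support
            cell_rules=rules,
        )
        model.method = "rflb"  # type: ignore[misc]
        res = model.fit(config=cfg, n_bootstrap=n_bootstrap)
        return BoundsResult(
            **{
                **res.__dict__,
                "extras": {"importance_report": report, "conditioning_scheme": scheme},
            }
        )


def rflb_bounds(
    ds: TrialDataset,
    config: AnalysisConfig | None = None,
    selection_rule: str = "both",
) -> tuple[BoundsResult, ImportanceReport, ConditioningScheme | None]:
    """Run the full RFLB pipeline; see :class:`RandomForestLeeBounds`."""
    model = RandomForestLeeBounds(ds, config, selection_rule)
    res = model.fit()
    return res, model.report_, model.scheme_


# ---------------------------------------------------------------------------
# Export


def export_importance_graph(
    report: ImportanceReport,
    path: str | Path,
    include_treatment: bool = True,
    plot: bool = False,
) -> None:
    """Write importance-graph data (bars sorted descending) as JSON, optional PNG.

    For conditioning decisions only background characteristics matter, so the
    treatment bar can be excluded with ``include_treatment=False``.
    """
    path = Path(path)
    bars = dict(report.importances)
    bars["(random benchmark)"] = report.benchmark_importance
    if include_treatment:
        bars["treatment"] = report.treatment_importance
    ordered = sorted(bars.items(), key=lambda kv: kv[1], reverse=True)
    payload = {
        "bars": [{"variable": k, "importance": v} for k, v in ordered],
        "interaction_bars": [
            {"variable": f"treatment*{k}", "importance": v}
            for k, v in sorted(
                report.interaction_importances.items(), key=lambda kv: kv[1], reverse=True
            )
        ]
        + [
            {
                "variable": "treatment*(random benchmark)",
                "importance": report.interaction_benchmark_importance,
            }
        ],
        "report": report.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2))
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = [k for k, _ in ordered][::-1]
        vals = [v for _, v in ordered][::-1]
        colors = ["crimson" if n == "(random benchmark)" else "steelblue" for n in names]
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(names) + 1.5))
        ax.barh(names, vals, color=colors)
        ax.set_xlabel("normalized importance (max = 1)")
        ax.set_title("Attrition importance graph")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)
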