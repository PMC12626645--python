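"""Drivers of community stability: keystone importance and path modelling.

Keystone importance follows the classic random-forest permutation scheme:
for each regression tree (bagged CART), the out-of-bag mean squared error is
compared before and after permuting one predictor; %IncMSE is the mean
relative OOB-MSE increase across trees, in percent.  Significance is
assessed rfPermute-style by refitting the whole forest on permuted
responses and ranking the observed importance in that null distribution.

Environmental variables enter the path model only after a greedy forward
selection on adjusted R-squared with a permutation acceptance test.  The
path model itself is a piecewise system of ordinary least-squares equations
on z-scored variables over a directed acyclic graph: each equation is fit
separately, coefficients are standardized path weights, and direct,
indirect (sum over directed paths of coefficient products) and total
effects are reported per source-sink pair.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .errors import InvalidInputError

__all__ = [
    "keystone_importance",
    "forward_select",
    "PathModel",
    "PathModelResults",
]


def _forest_inc_mse(
    x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean percent OOB-MSE increase per column over a bagged CART forest."""
    n, p = x.shape
    max_features = max(1, p // 3)  # regression-forest convention: mtry = p/3
    inc = np.zeros(p)
    used = np.zeros(p)
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        if oob.sum() < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(x[boot], y[boot])
        raw = tree.tree_  # bypass per-call input validation on tiny OOB sets
        x_oob = x32[oob]
        y_oob = y[oob]
        mse0 = np.mean((y_oob - raw.predict(x_oob).ravel()) ** 2)
        if mse0 == 0:
            mse0 = 1e-12
        order = rng.permutation(oob.sum())
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[order, j]
            mse_j = np.mean((y_oob - raw.predict(x_perm).ravel()) ** 2)
            inc[j] += 100.0 * (mse_j - mse0) / mse0
            used[j] += 1
    return inc / np.maximum(used, 1)


def keystone_importance(
    x,
    y,
    n_trees: int = 500,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """%IncMSE of each keystone taxon for a per-sample stability response.

    Parameters
    ----------
    x
        DataFrame (samples x keystone taxa) of abundances.
    y
        Per-sample stability response (e.g. N:P cohesion).

    Returns a table indexed by keystone with columns ``inc_mse_pct`` and
    ``permutation_p``.
    """
    x = pd.DataFrame(x)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 10:
        raise InvalidInputError("need at least 10 samples")
    if x.shape[1] < 1:
        raise InvalidInputError("need at least one keystone column")
    if len(y) != x.shape[0]:
        raise InvalidInputError("response length does not match sample count")
    if np.all(y == y[0]):
        raise InvalidInputError("constant response")
    rng = np.random.default_rng(seed)
    xv = x.to_numpy(dtype=float)
    obs = _forest_inc_mse(xv, y, n_trees, rng)
    hits = np.zeros(len(obs))
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        null = _forest_inc_mse(xv, y_perm, n_trees, rng)
        hits += null >= obs
    p = (1 + hits) / (1 + n_perm)
    return pd.DataFrame(
        {"inc_mse_pct": obs, "permutation_p": p}, index=list(x.columns)
    )


def _adj_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Adjusted R^2 of OLS with intercept; returns (adj_r2, rank)."""
    n = len(y)
    design = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0, rank
    r2 = 1 - ss_res / ss_tot
    k = design.shape[1] - 1
    if n - k - 1 <= 0:
        return -np.inf, rank
    return 1 - (1 - r2) * (n - 1) / (n - k - 1), rank


def forward_select(
    env,
    response,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[str]:
    """Greedy forward selection of environmental variables.

    At each step the candidate giving the largest adjusted-R^2 gain is
    tested by permuting that candidate's values ``n_perm`` times; it is
    accepted only when the permutation p-value is <= ``alpha`` and adjusted
    R^2 increased.  Ties break by column order.  Collinear candidates
    (design rank-deficient to machine precision) are skipped with a
    warning.
    """
    env = pd.DataFrame(env)
    y = np.asarray(response, dtype=float)
    if env.shape[1] < 2:
        raise InvalidInputError("need at least 2 candidate variables")
    if len(y) <= env.shape[1] + 2:
        raise InvalidInputError("need n > candidates + 2 samples")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    current_adj = 0.0
    candidates = list(env.columns)
    while candidates:
        best = None
        best_adj = current_adj
        x_sel = env[selected].to_numpy(dtype=float) if selected else np.empty((len(y), 0))
        for name in candidates:
            x_try = np.column_stack([x_sel, env[name].to_numpy(dtype=float)])
            adj, rank = _adj_r2(x_try, y)
            if rank < x_try.shape[1] + 1:
                warnings.warn(f"candidate {name!r} collinear with selection; skipped",
                              stacklevel=2)
                continue
            if adj > best_adj + 1e-12:
                best = name
                best_adj = adj
        if best is None:
            break
        x_best = env[best].to_numpy(dtype=float)
        obs_gain = best_adj - current_adj
        hits = 0
        for _ in range(n_perm):
            x_perm = np.column_stack([x_sel, rng.permutation(x_best)])
            adj_perm, _ = _adj_r2(x_perm, y)
            if adj_perm - current_adj >= obs_gain:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            break
        selected.append(best)
        candidates.remove(best)
        current_adj = best_adj
    return selected


_FORMULA_RE = re.compile(r"^\s*([\w.]+)\s*~\s*(.+)$")


def _parse_equations(equations) -> list[tuple[str, list[str]]]:
    parsed = []
    for eq in equations:
        if isinstance(eq, str):
            m = _FORMULA_RE.match(eq)
            if not m:
                raise InvalidInputError(f"cannot parse equation {eq!r}")
            response = m.group(1)
            predictors = [t.strip() for t in m.group(2).split("+") if t.strip()]
        else:
            response, predictors = eq[0], list(eq[1])
        if not predictors:
            raise InvalidInputError(f"equation for {response!r} has no predictors")
        parsed.append((response, predictors))
    return parsed


class PathModel:
    """Piecewise linear path model over a directed acyclic graph.

    Parameters
    ----------
    equations
        Iterable of formula strings (``"stability ~ MCs + diversity"``) or
        ``(response, [predictors])`` tuples; together they define the DAG.
    data
        DataFrame holding every variable; columns are z-scored before
        fitting, so coefficients are standardized path weights.
    """

    def __init__(self, equations, data: pd.DataFrame):
        self.equations = _parse_equations(equations)
        data = pd.DataFrame(data)
        missing = {
            v
            for resp, preds in self.equations
            for v in [resp, *preds]
            if v not in data.columns
        }
        if missing:
            raise InvalidInputError(f"variables missing from data: {sorted(missing)}")
        self.dag = nx.DiGraph()
        for resp, preds in self.equations:
            for p in preds:
                self.dag.add_edge(p, resp)
        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise InvalidInputError(f"path specification is cyclic: {cycle}")
        max_preds = max(len(p) for _, p in self.equations)
        if len(data) <= max_preds + 2:
            raise InvalidInputError("need n > max predictors + 2 samples")
        self.data = data

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, equations) -> "PathModel":
        return cls(equations, data)

    def fit(self) -> "PathModelResults":
        cols = sorted(self.dag.nodes)
        z = self.data[cols].astype(float)
        sd = z.std(ddof=1)
        if (sd == 0).any():
            # constant variable: standardized coefficient undefined; keep 0
            sd = sd.replace(0, 1.0)
        z = (z - z.mean()) / sd
        n = len(z)
        coef_rows = []
        r2 = {}
        weights = {}
        for resp, preds in self.equations:
            x = np.column_stack([np.ones(n), z[preds].to_numpy()])
            y = z[resp].to_numpy()
            beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            dof = n - x.shape[1]
            ss_res = float(resid @ resid)
            ss_tot = float((y**2).sum())  # z-scored: mean 0
            r2[resp] = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
            sigma2 = ss_res / dof if dof > 0 else np.nan
            xtx_inv = np.linalg.pinv(x.T @ x)
            se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
            for i, pred in enumerate(preds, start=1):
                b = float(beta[i])
                s = float(se[i])
                if ss_res <= 1e-12 * max(ss_tot, 1.0):
                    t, p = np.inf * np.sign(b) if b else 0.0, 0.0
                else:
                    t = b / s if s > 0 else np.inf * np.sign(b)
                    p = 2 * stats.t.sf(abs(t), dof) if dof > 0 else np.nan
                weights[(pred, resp)] = b
                coef_rows.append(
                    {
                        "response": resp,
                        "predictor": pred,
                        "coefficient": b,
                        "se": s,
                        "t": float(t),
                        "p": float(p),
                    }
                )
        return PathModelResults(
            model=self,
            coefficients=pd.DataFrame(coef_rows),
            r_squared=pd.Series(r2),
            _weights=weights,
        )


@dataclass
class PathModelResults:
    """Fitted standardized path model."""

    model: PathModel
    coefficients: pd.DataFrame
    r_squared: pd.Series
    _weights: dict = field(repr=False)

    def direct_effect(self, source: str, sink: str) -> float:
        return self._weights.get((source, sink), 0.0)

    def indirect_effect(self, source: str, sink: str) -> float:
        total = 0.0
        for path in nx.all_simple_paths(self.model.dag, source, sink):
            if len(path) < 3:
                continue
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= self._weights[(a, b)]
            total += prod
        return total

    def total_effect(self, source: str, sink: str) -> float:
        return self.direct_effect(source, sink) + self.indirect_effect(source, sink)

    def effects_table(self) -> pd.DataFrame:
        rows = []
        nodes = list(nx.topological_sort(self.model.dag))
        for src in nodes:
            for dst in nodes:
                if src == dst or not nx.has_path(self.model.dag, src, dst):
                    continue
                rows.append(
                    {
                        "source": src,
                        "sink": dst,
                        "direct": self.direct_effect(src, dst),
                        "indirect": self.indirect_effect(src, dst),
                        "total": self.total_effect(src, dst),
                    }
                )
        return pd.DataFrame(rows, columns=["source", "sink", "direct", "indirect", "total"])

    def summary(self) -> str:
        lines = ["Standardized path model", "=" * 55]
        for resp, _ in self.model.equations:
            lines.append(f"{resp}  (R^2 = {self.r_squared[resp]:.3f})")
            sub = self.coefficients[self.coefficients["response"] == resp]
            for _, row in sub.iterrows():
                lines.append(
                    f"  {row['predictor']:>16s} -> {resp}: "
                    f"beta = {row['coefficient']:+.3f}  (p = {row['p']:.4f})"
                )
        lines.append("-" * 55)
        eff = self.effects_table()
        for _, row in eff.iterrows():
            lines.append(
                f"  {row['source']} => {row['sink']}: direct {row['direct']:+.3f}, "
                f"indirect {row['indirect']:+.3f}, total {row['total']:+.3f}"
            )
        return "\n".join(lines)


def fit_path_model(equations, data: pd.DataFrame) -> PathModelResults:
    """Convenience wrapper: build and fit a :class:`PathModel`."""
    return PathModel(equations, data).fit()
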