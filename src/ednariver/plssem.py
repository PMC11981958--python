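"""PLS path modeling (PLS-SEM) with formative (Mode B) and reflective
(Mode A) blocks, Lohmöller's iterative estimation, effect decomposition and
permutation inference.

The default model mirrors the elevation → footprint → water-quality →
biodiversity structure: elevation and footprint are single-indicator blocks,
water quality (TP, TN, BOD5, TOC) and biodiversity (TD, FD, GD) are
formative composites.  Latent scores are standardized; path coefficients are
per-equation OLS of each endogenous latent on its predecessors, so
single-indicator models collapse to standardized path analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six structural paths of the default model, in estimation order.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("elevation", "footprint"),
    ("elevation", "water_quality"),
    ("footprint", "water_quality"),
    ("elevation", "biodiversity"),
    ("footprint", "biodiversity"),
    ("water_quality", "biodiversity"),
)

DEFAULT_BLOCKS: dict[str, list[str]] = {
    "elevation": ["elevation"],
    "footprint": ["footprint"],
    "water_quality": ["TP", "TN", "BOD5", "TOC"],
    "biodiversity": ["TD", "FD", "GD"],
}


@dataclass
class PathModel:
    """Latent blocks, modes and the acyclic inner structure of a PLS model."""

    latents: list[str]
    blocks: dict[str, list[str]]
    edges: list[tuple[str, str]]
    modes: dict[str, str] = field(default_factory=dict)  # 'A' or 'B'
    scheme: str = "centroid"  # centroid | factorial | path

    def __post_init__(self) -> None:
        for lv in self.latents:
            self.modes.setdefault(lv, "B")
            if lv not in self.blocks or not self.blocks[lv]:
                raise ValueError(f"latent {lv!r} has no indicator block")
        seen: set[str] = set()
        for lv in self.latents:
            overlap = seen & set(self.blocks[lv])
            if overlap:
                raise ValueError(f"indicators in more than one block: {sorted(overlap)}")
            seen |= set(self.blocks[lv])
        order = {lv: i for i, lv in enumerate(self.latents)}
        for src, dst in self.edges:
            if order[src] >= order[dst]:
                raise ValueError(
                    f"edge {src}->{dst} violates the latent ordering (inner model must be acyclic)"
                )

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, d in self.edges if d == latent]

    def successors(self, latent: str) -> list[str]:
        return [d for s, d in self.edges if s == latent]

    def neighbours(self, latent: str) -> list[str]:
        return self.predecessors(latent) + self.successors(latent)

    @property
    def exogenous(self) -> list[str]:
        return [lv for lv in self.latents if not self.predecessors(lv)]

    @property
    def endogenous(self) -> list[str]:
        return [lv for lv in self.latents if self.predecessors(lv)]


def default_model(scheme: str = "centroid", modes: dict[str, str] | None = None) -> PathModel:
    """The elevation / footprint / water-quality / biodiversity path model."""
    return PathModel(
        latents=list(DEFAULT_BLOCKS),
        blocks={k: list(v) for k, v in DEFAULT_BLOCKS.items()},
        edges=list(DEFAULT_EDGES),
        modes=dict(modes or {}),
        scheme=scheme,
    )


@dataclass
class PLSResult:
    model: PathModel
    outer_weights: dict[str, pd.Series]
    loadings: dict[str, pd.Series]
    scores: pd.DataFrame  # n × latents, unit variance
    paths: pd.DataFrame   # columns: source, target, coefficient
    r_squared: dict[str, float]
    iterations: int
    converged: bool

    def path(self, src: str, dst: str) -> float:
        row = self.paths[(self.paths.source == src) & (self.paths.target == dst)]
        if row.empty:
            raise KeyError(f"no path {src}->{dst}")
        return float(row.coefficient.iloc[0])


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant indicator column")
    return (X - mu) / sd


def fit_plspm(
    data: pd.DataFrame,
    model: PathModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PLSResult:
    """Estimate a PLS path model by Lohmöller's alternating algorithm.

    Outer weights start at 1; latent scores are standardized weighted sums of
    their (internally standardized) block indicators; inner weights follow
    the chosen scheme (centroid by default: the sign of the score correlation
    between adjacent latents); the outer update is Mode A (indicator–score
    covariance) or Mode B (multivariate regression of the inner proxy on the
    block).  Iteration stops when the largest outer-weight change is below
    ``tol``.  Non-convergence is flagged on the result, not raised.
    """
    model = model or default_model()
    if data.isna().any().any():
        raise ValueError("missing cells in indicator data")
    n = len(data)
    blocks_X = {}
    for lv in model.latents:
        cols = model.blocks[lv]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing indicator columns: {missing}")
        blocks_X[lv] = _standardize(data[cols].values.astype(float))

    weights = {lv: np.ones(blocks_X[lv].shape[1]) for lv in model.latents}

    def scores_from(w: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for lv in model.latents:
            s = blocks_X[lv] @ w[lv]
            sd = s.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate score for {lv!r}")
            out[lv] = (s - s.mean()) / sd
        return out

    def align_sign(lv: str, w: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # convention: each composite points in the direction of its block
        corr_sum = sum(
            float(np.corrcoef(blocks_X[lv][:, j], score)[0, 1])
            for j in range(blocks_X[lv].shape[1])
        )
        if corr_sum < 0:
            return -w, -score
        return w, score

    converged = False
    it = 0
    scores = scores_from(weights)
    for it in range(1, max_iter + 1):
        # inner estimation
        inner: dict[str, np.ndarray] = {}
        for lv in model.latents:
            z = np.zeros(n)
            for nb in model.neighbours(lv):
                r = float(np.corrcoef(scores[lv], scores[nb])[0, 1])
                if model.scheme == "centroid":
                    e = np.sign(r) if r != 0 else 1.0
                elif model.scheme == "factorial":
                    e = r
                elif model.scheme == "path":
                    e = None  # resolved below
                else:
                    raise ValueError(f"unknown scheme {model.scheme!r}")
                if e is not None:
                    z += e * scores[nb]
            if model.scheme == "path":
                preds = model.predecessors(lv)
                if preds:
                    Xp = np.column_stack([scores[p] for p in preds])
                    beta, *_ = np.linalg.lstsq(Xp, scores[lv], rcond=None)
                    z += Xp @ beta
                for succ in model.successors(lv):
                    r = float(np.corrcoef(scores[lv], scores[succ])[0, 1])
                    z += r * scores[succ]
            sd = z.std(ddof=1)
            inner[lv] = (z - z.mean()) / sd if sd > 0 else scores[lv]
        # outer estimation
        new_weights = {}
        for lv in model.latents:
            X = blocks_X[lv]
            if model.modes[lv].upper() == "A":
                w = X.T @ inner[lv] / (n - 1)
            else:  # Mode B
                w, *_ = np.linalg.lstsq(X, inner[lv], rcond=None)
            s = X @ w
            sd = s.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate composite for {lv!r}")
            w = w / sd
            score = (X @ w) - (X @ w).mean()
            w, score = align_sign(lv, w, score)
            new_weights[lv] = w
        delta = max(
            float(np.max(np.abs(new_weights[lv] - weights[lv]))) for lv in model.latents
        )
        weights = new_weights
        scores = scores_from(weights)
        for lv in model.latents:
            weights[lv], scores[lv] = align_sign(lv, weights[lv], scores[lv])
        if delta < tol:
            converged = True
            break

    score_df = pd.DataFrame({lv: scores[lv] for lv in model.latents}, index=data.index)

    # path coefficients: per-equation OLS on standardized scores
    rows = []
    r2 = {}
    for lv in model.endogenous:
        preds = model.predecessors(lv)
        Xp = np.column_stack([scores[p] for p in preds])
        beta, *_ = np.linalg.lstsq(Xp, scores[lv], rcond=None)
        fitted = Xp @ beta
        r2[lv] = float(1 - ((scores[lv] - fitted) ** 2).sum() / (scores[lv] ** 2).sum())
        for p, b in zip(preds, beta):
            rows.append({"source": p, "target": lv, "coefficient": float(b)})
    paths = pd.DataFrame(rows, columns=["source", "target", "coefficient"])

    outer = {
        lv: pd.Series(weights[lv], index=model.blocks[lv]) for lv in model.latents
    }
    loadings = {
        lv: pd.Series(
            [float(np.corrcoef(blocks_X[lv][:, j], scores[lv])[0, 1]) for j in range(blocks_X[lv].shape[1])],
            index=model.blocks[lv],
        )
        for lv in model.latents
    }
    return PLSResult(
        model=model,
        outer_weights=outer,
        loadings=loadings,
        scores=score_df,
        paths=paths,
        r_squared=r2,
        iterations=it,
        converged=converged,
    )


def effects_decomposition(result: PLSResult, model: PathModel | None = None) -> pd.DataFrame:
    """Direct, indirect and total effects for every ordered latent pair.

    The indirect effect of A on C is the sum over all directed paths of
    length ≥ 2 of the product of edge coefficients; total = direct + indirect.
    """
    model = model or result.model
    coef = {
        (r.source, r.target): r.coefficient for r in result.paths.itertuples(index=False)
    }

    def paths_between(src: str, dst: str) -> list[list[str]]:
        out: list[list[str]] = []

        def walk(node: str, trail: list[str]) -> None:
            if node == dst:
                out.append(trail[:])
                return
            for nxt in model.successors(node):
                walk(nxt, trail + [nxt])

        walk(src, [src])
        return out

    rows = []
    order = {lv: i for i, lv in enumerate(model.latents)}
    for src in model.latents:
        for dst in model.latents:
            if order[src] >= order[dst]:
                continue
            direct = coef.get((src, dst), 0.0)
            indirect = 0.0
            for trail in paths_between(src, dst):
                if len(trail) <= 2:
                    continue
                prod = 1.0
                for a, b in zip(trail, trail[1:]):
                    prod *= coef.get((a, b), 0.0)
                indirect += prod
            if direct == 0.0 and indirect == 0.0 and (src, dst) not in coef:
                if not paths_between(src, dst):
                    continue
            rows.append(
                {
                    "relation": f"{src} -> {dst}",
                    "direct": direct,
                    "indirect": indirect,
                    "total": direct + indirect,
                }
            )
    return pd.DataFrame(rows, columns=["relation", "direct", "indirect", "total"])


def permutation_test(
    data: pd.DataFrame,
    model: PathModel | None = None,
    n_perm: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Permutation p-values per structural path.

    The rows of the exogenous block(s) are permuted jointly ``n_perm`` times
    and the model refitted; p = (1 + #{|coef_perm| ≥ |coef_obs|}) / (n_perm + 1).
    """
    model = model or default_model()
    base = fit_plspm(data, model, tol=tol, max_iter=max_iter)
    obs = {
        (r.source, r.target): abs(r.coefficient)
        for r in base.paths.itertuples(index=False)
    }
    exo_cols = [c for lv in model.exogenous for c in model.blocks[lv]]
    rng = np.random.default_rng(seed)
    exceed = {key: 0 for key in obs}
    for _ in range(n_perm):
        perm = data.copy()
        idx = rng.permutation(len(data))
        perm[exo_cols] = data[exo_cols].values[idx]
        res = fit_plspm(perm, model, tol=tol, max_iter=max_iter)
        for r in res.paths.itertuples(index=False):
            if abs(r.coefficient) >= obs[(r.source, r.target)]:
                exceed[(r.source, r.target)] += 1
    rows = [
        {
            "source": s,
            "target": d,
            "coefficient": float(base.path(s, d)),
            "p_perm": (1 + exceed[(s, d)]) / (n_perm + 1),
        }
        for (s, d) in obs
    ]
    return pd.DataFrame(rows, columns=["source", "target", "coefficient", "p_perm"])
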