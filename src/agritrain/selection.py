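"""Grouped design matrices and penalized input selection.

Builds treatment-coded (reference-level) dummy designs in which all columns
of a factor, or of a factor-pair interaction, form one penalty group, and
selects model inputs per outcome by solving group-penalized least squares
along a regularization path with one of three penalties:

* group Lasso — groupwise soft thresholding,
* group MCP   — groupwise firm thresholding (concavity ``gamma``),
* group SCAD  — groupwise three-piece thresholding (concavity ``gamma``).

The objective is

    (1 / 2n) * ||y - b0 - X b||^2  +  lambda * sum_g sqrt(K_g) * ||b_g||_2

with ``K_g`` the number of columns of group ``g`` and the intercept
unpenalized. The solver is block coordinate descent with warm starts along
a decreasing lambda grid; each group is orthonormalized (``X_g' X_g / n =
I``) before thresholding and back-transformed, the standard device for
group penalties on correlated columns. The regularization parameter is
chosen by k-fold cross-validation (CV-error minimizer), the penalty among
the three by held-out test-set error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .events import DEFAULT_SCHEMA, EventTable

# ---------------------------------------------------------------------------
# Design specification and grouped dummy coding
# ---------------------------------------------------------------------------

DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("division", "time_bin"),
    ("division", "venue"),
    ("division", "trainer_gender"),
)


@dataclass(frozen=True)
class DesignSpec:
    """Factors, interactions and reference levels of the candidate design."""

    main_factors: tuple[str, ...] = tuple(DEFAULT_SCHEMA)
    interactions: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS
    schema: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMA))
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair in self.interactions:
            for f in pair:
                if f not in self.main_factors:
                    raise ValueError(
                        f"interaction factor {f!r} not among main factors")
        for f, lvl in self.reference.items():
            if lvl not in self.schema[f]:
                raise ValueError(f"invalid reference level {lvl!r} for {f!r}")

    def ref(self, factor: str) -> str:
        return self.reference.get(factor, self.schema[factor][0])

    def group_names(self) -> list[str]:
        return list(self.main_factors) + [f"{a}:{b}" for a, b in self.interactions]


@dataclass
class GroupedDesign:
    """Dummy-coded design with a factor-group index.

    ``X`` excludes the intercept (handled unpenalized by the solvers);
    ``groups[j]`` is the group id of column ``j`` and ``group_names[g]``
    the factor or interaction it codes.
    """

    X: np.ndarray
    columns: list[str]
    groups: np.ndarray
    group_names: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_cols(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.groups == g)


def _dummy_block(levels_series, factor: str, levels: tuple[str, ...], ref: str):
    cols, names = [], []
    values = np.asarray(levels_series)
    valid = set(levels)
    seen = set(np.unique(values).tolist())
    bad = seen - valid
    if bad:
        raise ValueError(f"unseen level(s) for factor {factor!r}: {sorted(bad)}")
    for lvl in levels:
        if lvl == ref:
            continue
        cols.append((values == lvl).astype(float))
        names.append(f"{factor}[{lvl}]")
    return cols, names


def build_design(table: EventTable, spec: DesignSpec,
                 terms: list[str] | None = None) -> GroupedDesign:
    """Build the grouped treatment-coded design for (a subset of) the spec.

    A factor with L levels contributes L-1 columns in one group; an
    interaction of L1 x L2 levels contributes (L1-1)(L2-1) columns in one
    group. ``terms`` restricts to the named groups (default: all).
    """
    wanted = spec.group_names() if terms is None else list(terms)
    unknown = set(wanted) - set(spec.group_names())
    if unknown:
        raise ValueError(f"unknown design terms: {sorted(unknown)}")
    df = table.df
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[int] = []
    group_names: list[str] = []
    for name in wanted:
        gid = len(group_names)
        if ":" in name:
            fa, fb = name.split(":")
            ca, na = _dummy_block(df[fa].astype(str), fa, spec.schema[fa], spec.ref(fa))
            cb, nb = _dummy_block(df[fb].astype(str), fb, spec.schema[fb], spec.ref(fb))
            for xa, la in zip(ca, na):
                for xb, lb in zip(cb, nb):
                    cols.append(xa * xb)
                    names.append(f"{la}:{lb}")
                    groups.append(gid)
        else:
            block, bn = _dummy_block(df[name].astype(str), name,
                                     spec.schema[name], spec.ref(name))
            cols.extend(block)
            names.extend(bn)
            groups.extend([gid] * len(block))
        group_names.append(name)
    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return GroupedDesign(X=X, columns=names, groups=np.asarray(groups, dtype=int),
                         group_names=group_names)


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------

def split_train_test(table: EventTable, fraction: float = 0.8,
                     seed: int = 0) -> tuple[EventTable, EventTable]:
    """Seeded disjoint random split; train size = round(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = table.n_events
    if n == 0:
        raise ValueError("cannot split an empty table")
    n_train = int(np.floor(fraction * n + 0.5))  # round half up
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (EventTable(df=table.df.iloc[tr].reset_index(drop=True)),
            EventTable(df=table.df.iloc[te].reset_index(drop=True)))


# ---------------------------------------------------------------------------
# Group-penalized least squares path
# ---------------------------------------------------------------------------

METHODS = ("group_lasso", "group_mcp", "group_scad")
DEFAULT_GAMMA = {"group_mcp": 3.0, "group_scad": 4.0}


@dataclass
class PenaltyPath:
    """Solution path along a decreasing lambda grid.

    ``coefs[i]`` holds ``[intercept, beta]`` on the original column scale
    at ``lambdas[i]``; cross-validation fills ``cv_mean``/``cv_sd`` and
    ``lambda_star`` later.
    """

    method: str
    lambdas: np.ndarray
    coefs: np.ndarray            # (n_lambda, 1 + p)
    columns: list[str]
    groups: np.ndarray
    group_names: list[str]
    gamma: float | None
    converged: np.ndarray
    cv_mean: np.ndarray | None = None
    cv_sd: np.ndarray | None = None
    lambda_star: float | None = None

    def selected_groups(self, i: int) -> list[str]:
        beta = self.coefs[i, 1:]
        out = []
        for g, name in enumerate(self.group_names):
            if np.any(beta[self.groups == g] != 0.0):
                out.append(name)
        return out

    def coef_at(self, lam: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[i]


class _OrthoDesign:
    """Per-group orthonormalization X_g -> Q_g with Q_g'Q_g / n = I.

    Rank-deficient directions within a group (singular values below
    ``rcond * s_max``) are dropped; their original-scale coefficients are
    zero by construction.
    """

    def __init__(self, design: GroupedDesign, y: np.ndarray, rcond: float = 1e-10):
        X = design.X
        n = X.shape[0]
        self.n = n
        self.col_means = X.mean(axis=0)
        Xc = X - self.col_means
        self.y_mean = float(np.mean(y))
        self.yc = y - self.y_mean
        self.design = design
        self.Q_blocks: list[np.ndarray] = []
        self.back: list[np.ndarray] = []     # maps ortho coefs -> original coefs
        self.K = np.zeros(design.n_groups)   # original group sizes
        self.ortho_dim = np.zeros(design.n_groups, dtype=int)
        for g in range(design.n_groups):
            idx = design.group_cols(g)
            self.K[g] = len(idx)
            B = Xc[:, idx]
            U, s, Vt = np.linalg.svd(B, full_matrices=False)
            keep = s > (rcond * s[0] if s.size and s[0] > 0 else np.inf)
            U, s, Vt = U[:, keep], s[keep], Vt[keep]
            Q = np.sqrt(n) * U
            self.Q_blocks.append(Q)
            # B @ back = Q  =>  back = V diag(sqrt(n)/s)
            self.back.append(Vt.T * (np.sqrt(n) / s) if s.size else
                             np.zeros((len(idx), 0)))
            self.ortho_dim[g] = int(keep.sum())

    def lambda_max(self) -> float:
        lams = []
        for g, Q in enumerate(self.Q_blocks):
            if Q.shape[1] == 0:
                continue
            z = Q.T @ self.yc / self.n
            lams.append(np.linalg.norm(z) / np.sqrt(self.K[g]))
        return max(lams) if lams else 0.0

    def to_original(self, b_tilde: list[np.ndarray]) -> np.ndarray:
        """Return [intercept, beta] on the original column scale."""
        p = self.design.X.shape[1]
        beta = np.zeros(p)
        for g in range(self.design.n_groups):
            idx = self.design.group_cols(g)
            beta[idx] = self.back[g] @ b_tilde[g]
        b0 = self.y_mean - float(self.col_means @ beta)
        return np.concatenate(([b0], beta))


def _threshold(z: np.ndarray, lam_g: float, method: str, gamma: float | None
               ) -> np.ndarray:
    """Groupwise threshold of the orthonormal-coordinates update z."""
    nz = np.linalg.norm(z)
    if lam_g == 0.0 or nz == 0.0:
        return z
    if method == "group_lasso":
        return max(0.0, 1.0 - lam_g / nz) * z
    if method == "group_mcp":
        if nz <= gamma * lam_g:
            soft = max(0.0, nz - lam_g)
            return (gamma / (gamma - 1.0)) * (soft / nz) * z
        return z
    if method == "group_scad":
        if nz <= 2.0 * lam_g:
            return (max(0.0, nz - lam_g) / nz) * z
        if nz <= gamma * lam_g:
            soft = max(0.0, nz - gamma * lam_g / (gamma - 1.0))
            return ((gamma - 1.0) / (gamma - 2.0)) * (soft / nz) * z
        return z
    raise ValueError(f"unknown method {method!r}")


def default_lambda_grid(lam_max: float, n_lambda: int = 100,
                        min_ratio: float = 1e-3) -> np.ndarray:
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def fit_group_path(design: GroupedDesign, y: np.ndarray, method: str,
                   lambdas: np.ndarray | None = None,
                   gamma: float | None = None,
                   tol: float = 1e-8, max_iter: int = 10_000) -> PenaltyPath:
    """Solve the group-penalized least-squares path by warm-started BCD."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    gamma = DEFAULT_GAMMA.get(method) if gamma is None else gamma
    od = _OrthoDesign(design, y)
    if lambdas is None:
        lambdas = default_lambda_grid(od.lambda_max())
    lambdas = np.asarray(lambdas, dtype=float)
    G = design.n_groups
    b = [np.zeros(od.ortho_dim[g]) for g in range(G)]
    r = od.yc.copy()
    coefs = np.zeros((len(lambdas), 1 + design.X.shape[1]))
    converged = np.zeros(len(lambdas), dtype=bool)
    sqrtK = np.sqrt(od.K)
    for i, lam in enumerate(lambdas):
        for it in range(max_iter):
            delta = 0.0
            for g in range(G):
                Q = od.Q_blocks[g]
                if Q.shape[1] == 0:
                    continue
                z = b[g] + Q.T @ r / od.n
                b_new = _threshold(z, lam * sqrtK[g], method, gamma)
                step = b_new - b[g]
                ds = np.max(np.abs(step)) if step.size else 0.0
                if ds > 0:
                    r -= Q @ step
                    b[g] = b_new
                    delta = max(delta, ds)
            if delta < tol:
                converged[i] = True
                break
        coefs[i] = od.to_original(b)
    return PenaltyPath(method=method, lambdas=lambdas, coefs=coefs,
                       columns=design.columns, groups=design.groups,
                       group_names=design.group_names, gamma=gamma,
                       converged=converged)


# ---------------------------------------------------------------------------
# Cross-validation and model-accuracy metrics
# ---------------------------------------------------------------------------

def _predict(coefs: np.ndarray, X: np.ndarray) -> np.ndarray:
    return coefs[0] + X @ coefs[1:]


def cross_validate_lambda(design: GroupedDesign, y: np.ndarray, method: str,
                          folds: int = 10, seed: int = 0,
                          gamma: float | None = None,
                          lambdas: np.ndarray | None = None
                          ) -> PenaltyPath:
    """k-fold CV over the lambda grid; lambda_star minimizes mean CV error.

    The grid is fixed on the full data; per lambda the mean and SD over
    folds of the held-out mean squared error are recorded. Returns the
    full-data path annotated with the CV curve and ``lambda_star``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many observations as folds")
    full = fit_group_path(design, y, method, lambdas=lambdas, gamma=gamma)
    lambdas = full.lambdas
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    fold_err = np.zeros((folds, len(lambdas)))
    for k, test_idx in enumerate(fold_ids):
        if len(test_idx) == 0:
            raise ValueError("cross-validation fold with zero rows")
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        sub = GroupedDesign(X=design.X[mask], columns=design.columns,
                            groups=design.groups, group_names=design.group_names)
        path = fit_group_path(sub, y[mask], method, lambdas=lambdas, gamma=gamma)
        Xte, yte = design.X[test_idx], y[test_idx]
        for i in range(len(lambdas)):
            resid = yte - _predict(path.coefs[i], Xte)
            fold_err[k, i] = float(np.mean(resid ** 2))
    full.cv_mean = fold_err.mean(axis=0)
    full.cv_sd = fold_err.std(axis=0, ddof=1)
    full.lambda_star = float(lambdas[int(np.argmin(full.cv_mean))])
    return full


def evaluate_smse(coefs: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
                  ) -> float:
    """Test-set accuracy as root-mean-square error on the count scale."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    resid = np.asarray(y_test, dtype=float) - _predict(coefs, X_test)
    return float(np.sqrt(np.mean(resid ** 2)))


def evaluate_nmse(coefs: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
                  ) -> float:
    """Variance-normalized mean squared error (MSE / Var(y_test))."""
    y = np.asarray(y_test, dtype=float)
    resid = y - _predict(coefs, X_test)
    var = float(np.var(y))
    return float(np.mean(resid ** 2) / var) if var > 0 else float("inf")


# ---------------------------------------------------------------------------
# Full input-selection procedure
# ---------------------------------------------------------------------------

_TIE_ORDER = {"group_mcp": 0, "group_scad": 1, "group_lasso": 2}


@dataclass
class SelectionResult:
    """Outcome of the shrinkage comparison for one response."""

    outcome: str
    chosen_method: str
    selected_groups: list[str]      # after weak-heredity completion
    per_method: dict[str, dict]     # method -> {smse, nmse, lambda_star, groups, ...}
    split_seed: int
    cv_seed: int
    fraction: float

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "chosen_method": self.chosen_method,
            "selected_groups": self.selected_groups,
            "per_method": self.per_method,
            "split_seed": self.split_seed,
            "cv_seed": self.cv_seed,
            "fraction": self.fraction,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def weak_heredity(groups: list[str]) -> list[str]:
    """Add parent main effects of any selected interaction, preserving order."""
    out = list(groups)
    for g in groups:
        if ":" in g:
            for parent in g.split(":"):
                if parent not in out:
                    out.append(parent)
    return out


def choose_method(per_method: dict[str, dict]) -> str:
    """Minimum SMSE; ties broken toward fewer groups, then MCP, SCAD, Lasso."""
    return min(per_method,
               key=lambda m: (per_method[m]["smse"],
                              len(per_method[m]["selected_groups"]),
                              _TIE_ORDER.get(m, 99)))


def select_inputs(table: EventTable, spec: DesignSpec, outcome: str,
                  methods: tuple[str, ...] = METHODS, seed: int = 0,
                  fraction: float = 0.8, folds: int = 10) -> SelectionResult:
    """Run the full shrinkage comparison for one outcome.

    Splits the table 80/20, cross-validates lambda per penalty on the
    training part, scores each penalty's CV-selected model on the test
    part by SMSE, picks the winner, and completes the winning group set
    under weak heredity.
    """
    if outcome not in ("males", "females"):
        raise ValueError("outcome must be 'males' or 'females'")
    train, test = split_train_test(table, fraction=fraction, seed=seed)
    cv_seed = seed + 1
    d_train = build_design(train, spec)
    d_test = build_design(test, spec)
    y_train = train.df[outcome].to_numpy(dtype=float)
    y_test = test.df[outcome].to_numpy(dtype=float)
    per_method: dict[str, dict] = {}
    for method in methods:
        path = cross_validate_lambda(d_train, y_train, method,
                                     folds=folds, seed=cv_seed)
        i_star = int(np.argmin(np.abs(path.lambdas - path.lambda_star)))
        coefs = path.coefs[i_star]
        per_method[method] = {
            "lambda_star": path.lambda_star,
            "smse": evaluate_smse(coefs, d_test.X, y_test),
            "nmse": evaluate_nmse(coefs, d_test.X, y_test),
            "selected_groups": path.selected_groups(i_star),
            "cv_mean": path.cv_mean.tolist(),
            "cv_sd": path.cv_sd.tolist(),
            "lambdas": path.lambdas.tolist(),
            "n_converged": int(path.converged.sum()),
        }
    chosen = choose_method(per_method)
    selected = weak_heredity(per_method[chosen]["selected_groups"])
    return SelectionResult(outcome=outcome, chosen_method=chosen,
                           selected_groups=selected, per_method=per_method,
                           split_seed=seed, cv_seed=cv_seed, fraction=fraction)
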