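"""Gender-specific quasi-Poisson attendance models.

Each model is a log-link count GLM for one outcome (male or female
attendance) on a selected set of factor/interaction terms. Coefficients
are the Poisson maximum-likelihood estimates (IRLS); overdispersion enters
only through the dispersion parameter ``phi`` = Pearson chi-square /
(n - p), which scales the coefficient covariance but not the point
estimates — the quasi-likelihood property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import statsmodels.api as sm

from .events import EventTable
from .selection import DesignSpec, build_design

#: Term sets used when the user skips data-driven input selection:
#: the male model keeps trainer gender, venue, division, time of day and
#: the division-by-time interaction (with all lower-order terms); the
#: female model keeps trainer gender, time of day, month, venue and
#: division as main effects.
DEFAULT_MALE_TERMS: tuple[str, ...] = (
    "trainer_gender", "venue", "division", "time_bin", "division:time_bin")
DEFAULT_FEMALE_TERMS: tuple[str, ...] = (
    "trainer_gender", "time_bin", "month", "venue", "division")


@dataclass
class FittedAttendanceModel:
    """Fitted log-link count GLM with quasi-Poisson dispersion."""

    outcome: str
    terms: tuple[str, ...]
    columns: list[str]          # dummy columns, excluding intercept
    coefficients: np.ndarray    # [intercept, beta] aligned to columns
    dispersion: float
    covariance: np.ndarray      # (1+p, 1+p), scaled by dispersion
    n_obs: int
    converged: bool
    spec: DesignSpec

    # -- prediction --------------------------------------------------------

    def _row(self, event_config: dict[str, str]) -> np.ndarray:
        """Design row [1, x] for one covariate configuration."""
        needed = {f for t in self.terms for f in t.split(":")}
        missing = [f for f in needed if f not in event_config]
        if missing:
            raise ValueError(f"event configuration missing level(s) for {missing}")
        for f in needed:
            if event_config[f] not in self.spec.schema[f]:
                raise ValueError(
                    f"unknown level {event_config[f]!r} for factor {f!r}")
        x = np.zeros(1 + len(self.columns))
        x[0] = 1.0
        for j, col in enumerate(self.columns):
            hit = all(event_config[part[:-1].split("[", 1)[0]]
                      == part[:-1].split("[", 1)[1]
                      for part in col.split(":"))
            x[1 + j] = 1.0 if hit else 0.0
        return x

    def design_rows(self, configs: list[dict[str, str]]) -> np.ndarray:
        return np.vstack([self._row(c) for c in configs])

    def predict_mean(self, event_config: dict[str, str],
                     with_se: bool = False):
        """Expected count exp(x'beta); SE by the delta method on request."""
        x = self._row(event_config)
        mu = float(np.exp(x @ self.coefficients))
        if not with_se:
            return mu
        se = mu * float(np.sqrt(x @ self.covariance @ x))
        return mu, se

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "terms": list(self.terms),
            "columns": self.columns,
            "coefficients": self.coefficients.tolist(),
            "dispersion": self.dispersion,
            "covariance": self.covariance.tolist(),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "schema": {k: list(v) for k, v in self.spec.schema.items()},
            "reference": {f: self.spec.ref(f) for f in self.spec.schema},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedAttendanceModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        schema = {k: tuple(v) for k, v in payload["schema"].items()}
        spec = DesignSpec(main_factors=tuple(schema), interactions=(),
                          schema=schema, reference=payload["reference"])
        return cls(outcome=payload["outcome"], terms=tuple(payload["terms"]),
                   columns=payload["columns"],
                   coefficients=np.asarray(payload["coefficients"]),
                   dispersion=payload["dispersion"],
                   covariance=np.asarray(payload["covariance"]),
                   n_obs=payload["n_obs"], converged=payload["converged"],
                   spec=spec)


def fit_quasipoisson(table: EventTable, terms, outcome: str,
                     spec: DesignSpec | None = None,
                     max_iter: int = 100, tol: float = 1e-8
                     ) -> FittedAttendanceModel:
    """Fit the quasi-Poisson GLM for one outcome on the given terms.

    Point estimates come from Poisson IRLS; ``phi`` is the Pearson
    statistic over its degrees of freedom and scales the covariance.
    Raises on rank-deficient designs (naming the aliased columns) and on
    non-convergence.
    """
    if outcome not in ("males", "females"):
        raise ValueError("outcome must be 'males' or 'females'")
    # interactions referenced by the terms must be constructible
    inters = tuple(tuple(t.split(":")) for t in terms if ":" in t)
    if spec is None:
        spec = DesignSpec(interactions=inters)
    elif any(i not in spec.interactions for i in inters):
        spec = DesignSpec(main_factors=spec.main_factors, interactions=inters,
                          schema=spec.schema, reference=spec.reference)
    design = build_design(table, spec, terms=list(terms))
    X = np.column_stack([np.ones(table.n_events), design.X])
    y = table.df[outcome].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more coefficients than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted(piv[rank:].tolist())
        names = ["intercept"] + design.columns
        raise ValueError("rank-deficient design; aliased columns: "
                         + ", ".join(names[j] for j in aliased))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
        maxiter=max_iter, tol=tol)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge within {max_iter} iterations")
    # Pearson dispersion; a degenerate perfect fit floors at a tiny value
    phi = max(float(res.pearson_chi2 / res.df_resid), np.finfo(float).tiny)
    return FittedAttendanceModel(
        outcome=outcome, terms=tuple(terms), columns=design.columns,
        coefficients=np.asarray(res.params), dispersion=phi,
        covariance=phi * np.asarray(res.cov_params()), n_obs=table.n_events,
        converged=bool(res.converged), spec=spec)


def predict_total(male_model: FittedAttendanceModel,
                  female_model: FittedAttendanceModel,
                  event_config: dict[str, str]) -> tuple[float, float, float]:
    """(total, female, proportion female) at one event configuration.

    Total attendance is the sum of the two model predictions; a zero
    total reports proportion 0.
    """
    m = male_model.predict_mean(event_config)
    f = female_model.predict_mean(event_config)
    total = m + f
    prop = f / total if total > 0 else 0.0
    return total, f, prop
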