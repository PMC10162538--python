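"""Bootstrap uncertainty for the fit-and-predict procedure.

Resamples events with replacement, refits both gender-specific GLMs on
each replicate with the model terms held fixed, and summarizes replicate
predictions over a mesh of event configurations by means and percentile
95% confidence intervals. Input selection is run once on the original
data, not per replicate (``reselect_per_replicate`` re-enables it for
sensitivity analysis at proportional cost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTable
from .models import FittedAttendanceModel, fit_quasipoisson
from .selection import DesignSpec, METHODS, select_inputs


@dataclass
class BootstrapEnsemble:
    """B replicate coefficient vectors for the male and female models."""

    male_model: FittedAttendanceModel      # fit on the original table
    female_model: FittedAttendanceModel
    male_coefs: np.ndarray                 # (B, 1 + p_male)
    female_coefs: np.ndarray               # (B, 1 + p_female)
    seed: int
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return self.male_coefs.shape[0]

    def predict(self, configs: list[dict[str, str]]
                ) -> tuple[np.ndarray, np.ndarray]:
        """(B, n_config) male and female replicate predictions."""
        Xm = self.male_model.design_rows(configs)
        Xf = self.female_model.design_rows(configs)
        return np.exp(self.male_coefs @ Xm.T), np.exp(self.female_coefs @ Xf.T)


def bootstrap_models(table: EventTable, male_terms, female_terms,
                     B: int = 1000, seed: int = 0,
                     spec: DesignSpec | None = None,
                     reselect_per_replicate: bool = False,
                     max_failure_rate: float = 0.05) -> BootstrapEnsemble:
    """Draw B resampled tables and refit both GLMs on each.

    Replicates whose fit fails to converge (or is rank-deficient, which
    resampling can cause for sparse cells) are redrawn; if redraws exceed
    ``max_failure_rate * B`` the run aborts with a diagnostic.
    """
    if table.n_events == 0:
        raise ValueError("cannot bootstrap an empty table")
    male_fit = fit_quasipoisson(table, male_terms, "males", spec=spec)
    female_fit = fit_quasipoisson(table, female_terms, "females", spec=spec)
    rng = np.random.default_rng(seed)
    n = table.n_events
    max_failures = int(np.ceil(max_failure_rate * B))
    mc = np.zeros((B, len(male_fit.coefficients)))
    fc = np.zeros((B, len(female_fit.coefficients)))
    failures = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        rep = EventTable(df=table.df.iloc[idx].reset_index(drop=True))
        try:
            m_terms, f_terms = male_terms, female_terms
            if reselect_per_replicate:
                m_terms = select_inputs(rep, spec or DesignSpec(), "males",
                                        METHODS, seed=int(rng.integers(2**31))
                                        ).selected_groups
                f_terms = select_inputs(rep, spec or DesignSpec(), "females",
                                        METHODS, seed=int(rng.integers(2**31))
                                        ).selected_groups
            m = fit_quasipoisson(rep, m_terms, "males", spec=spec)
            f = fit_quasipoisson(rep, f_terms, "females", spec=spec)
        except (ValueError, RuntimeError) as err:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"bootstrap aborted: {failures} replicate failures "
                    f"(> {max_failure_rate:.0%} of B={B}); last error: {err}")
            continue
        if reselect_per_replicate:
            # coefficient layout varies with reselected terms; store on the
            # original layout with absent columns at zero
            mc[b] = _align(m, male_fit)
            fc[b] = _align(f, female_fit)
        else:
            mc[b] = m.coefficients
            fc[b] = f.coefficients
        b += 1
    return BootstrapEnsemble(male_model=male_fit, female_model=female_fit,
                             male_coefs=mc, female_coefs=fc, seed=seed,
                             n_redrawn=failures)


def _align(rep: FittedAttendanceModel, base: FittedAttendanceModel) -> np.ndarray:
    out = np.zeros(len(base.coefficients))
    out[0] = rep.coefficients[0]
    pos = {c: j for j, c in enumerate(base.columns)}
    for j, col in enumerate(rep.columns):
        if col in pos:
            out[1 + pos[col]] = rep.coefficients[1 + j]
    return out


def summarize_mesh(ensemble: BootstrapEnsemble,
                   mesh: list[dict[str, str]],
                   ci: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Mean and percentile CI of total, female and proportion-female
    predictions at every mesh point.

    The proportion is computed per replicate (female / total) and then
    summarized. Percentiles use the linear-interpolation quantile rule.
    """
    if ensemble.B == 0:
        raise ValueError("empty ensemble")
    m_pred, f_pred = ensemble.predict(mesh)          # (B, n_mesh)
    total = m_pred + f_pred
    prop = np.where(total > 0, f_pred / total, 0.0)
    rows = []
    for j, cfg in enumerate(mesh):
        row = dict(cfg)
        for name, mat in (("total", total), ("female", f_pred), ("prop", prop)):
            lo, hi = np.percentile(mat[:, j], ci)
            row[f"{name}_mean"] = float(mat[:, j].mean())
            row[f"{name}_lo"] = float(lo)
            row[f"{name}_hi"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)
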