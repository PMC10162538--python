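"""Mesh enumeration, top-list ranking and mixing-policy simulation.

The discrete space of feasible training events is the Cartesian product of
the categorical axes retained by the two attendance models. Mesh points
are ranked by bootstrap-mean predicted total attendance and by predicted
female attendance; the X% mixing policy builds an event list of size N by
taking the top X% of the female ranking and the top (100-X)% of the total
ranking, trading total turnout against female participation. Scenario
metrics are summarized over bootstrap replicates with percentile 95%
confidence intervals and compared against the observed per-event averages
(122 total / 23 female under intuition-based scheduling).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEnsemble, summarize_mesh
from .events import DEFAULT_SCHEMA, FACTORS

#: Observed per-event averages under human-intuition scheduling.
DEFAULT_BENCHMARK: dict[str, float] = {"total": 122.0, "female": 23.0}

DEFAULT_N_MENU: tuple[int, ...] = (100, 50, 10)
DEFAULT_X_GRID: tuple[int, ...] = tuple(range(0, 101, 10))


def build_mesh(male_terms, female_terms,
               schema: dict[str, tuple[str, ...]] | None = None,
               month_fix: str = "jan2019") -> list[dict[str, str]]:
    """Enumerate event configurations over the union of retained factors.

    Factors appearing in neither model (after selection) are dropped from
    the mesh. Month is treated as an effect modifier rather than a free
    axis: when retained it is pinned to ``month_fix`` (default the latest
    study month) instead of multiplying the mesh size.
    """
    schema = schema or DEFAULT_SCHEMA
    used = {f for t in tuple(male_terms) + tuple(female_terms)
            for f in t.split(":")}
    axes = [f for f in FACTORS if f in used and f != "month"]
    if not axes and "month" not in used:
        raise ValueError("no factors retained by either model")
    configs = []
    for combo in itertools.product(*(schema[f] for f in axes)):
        cfg = dict(zip(axes, combo))
        if "month" in used:
            cfg["month"] = month_fix
        configs.append(cfg)
    return configs


def _config_key(row: pd.Series, axes: list[str]) -> tuple:
    return tuple(row[a] for a in axes)


@dataclass
class RankedList:
    """Mesh points in descending order of one bootstrap-mean criterion."""

    criterion: str                # "total" or "female"
    summary: pd.DataFrame         # sorted copy; original mesh index preserved
    axes: list[str] = field(default_factory=list)

    def top(self, n: int) -> pd.DataFrame:
        return self.summary.iloc[:n]

    def __len__(self) -> int:
        return len(self.summary)


def rank_mesh(summary: pd.DataFrame, criterion: str) -> RankedList:
    """Sort mesh points by criterion mean, with deterministic tie-breaks.

    Ties on the criterion break on the other criterion's mean, then on
    lexicographic configuration order, so top lists are reproducible.
    """
    if criterion not in ("total", "female"):
        raise ValueError("criterion must be 'total' or 'female'")
    other = "female" if criterion == "total" else "total"
    axes = [f for f in FACTORS if f in summary.columns]
    df = summary.copy()
    df["_key"] = [_config_key(r, axes) for _, r in df.iterrows()]
    df = df.sort_values(
        by=[f"{criterion}_mean", f"{other}_mean", "_key"],
        ascending=[False, False, True], kind="mergesort").drop(columns="_key")
    return RankedList(criterion=criterion, summary=df, axes=axes)


def mix_lists(total_list: RankedList, female_list: RankedList,
              N: int, X: float) -> pd.DataFrame:
    """Select N mesh points mixing the two rankings at fraction X%.

    ``k = round(X*N/100)`` (half rounds up) entries come from the top of
    the female list, the other ``N-k`` from the top of the total list.
    Configurations present in both sub-lists are deduplicated by
    backfilling from the next-ranked unused entries of the female list,
    preserving the female-emphasis intent of X.
    """
    if not 0 <= X <= 100:
        raise ValueError("X must lie in [0, 100]")
    if len(total_list) < N or len(female_list) < N:
        raise ValueError("ranked lists shorter than requested N")
    k = int(np.floor(X * N / 100.0 + 0.5))
    base = total_list.top(N - k)
    chosen = list(base.index)
    seen = set(chosen)
    for idx in female_list.summary.index:
        if len(chosen) >= N:
            break
        if idx not in seen:
            chosen.append(idx)
            seen.add(idx)
    if len(chosen) < N:
        raise ValueError("insufficient distinct mesh points to fill N")
    return pd.concat([base, female_list.summary.loc[[i for i in chosen
                                                     if i not in base.index]]])


def evaluate_scenario(selection: pd.DataFrame, ensemble: BootstrapEnsemble,
                      mesh: list[dict[str, str]],
                      ci: tuple[float, float] = (2.5, 97.5)) -> dict:
    """Bootstrap-summarized outcome metrics of one selected event list.

    Per replicate the selected configurations' predicted totals and female
    counts are averaged and the attendance-weighted proportion female
    (sum female / sum total) computed; metrics are replicate means with
    percentile CIs. The unweighted mean of per-event proportions is also
    reported.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    configs = [mesh[i] for i in selection.index]
    m_pred, f_pred = ensemble.predict(configs)
    total = m_pred + f_pred
    mean_total = total.mean(axis=1)              # per replicate
    mean_female = f_pred.mean(axis=1)
    tot_sum = total.sum(axis=1)
    prop_w = np.where(tot_sum > 0, f_pred.sum(axis=1) / tot_sum, 0.0)
    with np.errstate(invalid="ignore"):
        prop_u = np.where(total > 0, f_pred / total, 0.0).mean(axis=1)
    out: dict = {"n_selected": len(selection)}
    for name, vals in (("total", mean_total), ("female", mean_female),
                       ("prop", prop_w), ("prop_unweighted", prop_u)):
        lo, hi = np.percentile(vals, ci)
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_lo"] = float(lo)
        out[f"{name}_hi"] = float(hi)
    return out


def sweep(total_list: RankedList, female_list: RankedList,
          ensemble: BootstrapEnsemble, mesh: list[dict[str, str]],
          N_menu: tuple[int, ...] = DEFAULT_N_MENU,
          X_grid: tuple[int, ...] = DEFAULT_X_GRID) -> pd.DataFrame:
    """Trade-off table over list sizes N and mixing fractions X.

    One row per (N, X) cell with replicate-mean total attendance, female
    attendance and proportion female plus 95% CIs. List sizes exceeding
    the mesh are skipped with a warning.
    """
    rows = []
    for N in N_menu:
        if N > len(total_list):
            warnings.warn(f"list size N={N} exceeds mesh size "
                          f"{len(total_list)}; skipped")
            continue
        for X in X_grid:
            sel = mix_lists(total_list, female_list, N, X)
            metrics = evaluate_scenario(sel, ensemble, mesh)
            rows.append({"N": N, "X": X,
                         "mean_total": metrics["total_mean"],
                         "total_lo": metrics["total_lo"],
                         "total_hi": metrics["total_hi"],
                         "mean_female": metrics["female_mean"],
                         "female_lo": metrics["female_lo"],
                         "female_hi": metrics["female_hi"],
                         "prop_female": metrics["prop_mean"],
                         "prop_lo": metrics["prop_lo"],
                         "prop_hi": metrics["prop_hi"]})
    return pd.DataFrame(rows)


def benchmark_compare(scenario: dict, benchmark: dict[str, float] | None = None
                      ) -> dict[str, bool]:
    """Whether the scenario's lower 95% limits strictly exceed the
    observed intuition-scheduling averages."""
    benchmark = benchmark or DEFAULT_BENCHMARK
    lo_total = scenario.get("total_lo", scenario.get("total_lo", np.nan))
    lo_female = scenario.get("female_lo")
    return {"exceeds_total": bool(lo_total > benchmark["total"]),
            "exceeds_female": bool(lo_female > benchmark["female"])}


def balanced_selection(summary: pd.DataFrame, ensemble: BootstrapEnsemble,
                       N: int, X: float,
                       quota: dict[str, float]) -> pd.DataFrame:
    """Division-balanced variant: apply the mixing rule within each
    division to fill that division's quota of the N slots.

    ``quota`` maps division level to its share of N (summing to 1); seat
    counts are apportioned by largest remainder.
    """
    if abs(sum(quota.values()) - 1.0) > 1e-9:
        raise ValueError("quota shares must sum to 1")
    shares = {d: q * N for d, q in quota.items()}
    seats = {d: int(np.floor(s)) for d, s in shares.items()}
    leftover = N - sum(seats.values())
    for d in sorted(shares, key=lambda d: (shares[d] - seats[d], d),
                    reverse=True)[:leftover]:
        seats[d] += 1
    parts = []
    for division, n_d in seats.items():
        if n_d == 0:
            continue
        sub = summary[summary["division"] == division]
        if len(sub) < n_d:
            raise ValueError(
                f"quota infeasible: {n_d} slots but only {len(sub)} mesh "
                f"points in division {division!r}")
        parts.append(mix_lists(rank_mesh(sub, "total"),
                               rank_mesh(sub, "female"), n_d, X))
    return pd.concat(parts)


def top_list_table(ranked: RankedList, n: int = 10) -> pd.DataFrame:
    """Report-style top-n table: rank, configuration, prediction, CI."""
    crit = ranked.criterion
    rows = ranked.top(n).reset_index(drop=True)
    out = rows[ranked.axes].copy()
    out.insert(0, "rank", np.arange(1, len(rows) + 1))
    out[f"predicted_{crit}"] = rows[f"{crit}_mean"].round(0)
    out["ci_lo"] = rows[f"{crit}_lo"].round(0)
    out["ci_hi"] = rows[f"{crit}_hi"].round(0)
    return out
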