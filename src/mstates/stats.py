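"""Between-group inference for microstate parameters and connectivity.

Microstate parameters (Duration, Occurrence, Coverage) are compared with
the Mann-Whitney U test reported as an asymptotic Z (tie-corrected
variance, no continuity correction — the convention SPSS prints for its
"nonparametric test"), with exact enumeration available for small
samples. Pooled connectivity edge values are compared with a two-sample
Z test on summary statistics. Descriptive cohort tables round
percentages half-up, matching clinical reporting style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "mann_whitney",
    "two_sample_z",
    "compare_parameter_tables",
    "compare_connectivity_tables",
    "cohort_summary",
    "percent_display",
]


@dataclass
class GroupComparisonResult:
    metric: str
    state: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    statistic_type: str  # "U" or "Z"
    u: float | None
    z: float
    p: float
    n_x: int
    n_y: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError("group sizes must be positive")
        if not (np.isnan(self.p) or 0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")


def mann_whitney(
    x,
    y,
    metric: str = "",
    state: str = "",
    continuity: bool = False,
    exact: bool | None = None,
) -> GroupComparisonResult:
    """Mann-Whitney U with asymptotic Z (tie-corrected, two-sided).

    ``Z = (U1 - n1 n2 / 2) / sigma`` where ``U1`` counts wins of ``x``
    over ``y`` and ``sigma`` uses the tie-corrected variance
    ``n1 n2 / 12 * (n + 1 - sum(t^3 - t) / (n (n - 1)))``. No continuity
    correction by default (``continuity=True`` enables the 0.5 shift).
    ``exact=True`` (or ``exact=None`` with min(n) <= 8 and no ties)
    additionally computes the exact-enumeration p value, reported in
    place of the asymptotic one while Z is still returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    flags: list[str] = []
    if var <= 0:
        # every value identical in both groups
        z, p = 0.0, 1.0
        flags.append("degenerate")
    else:
        num = u1 - mu
        if continuity and num != 0:
            num -= 0.5 * np.sign(num)
        z = num / np.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    has_ties = bool(np.any(tie_counts > 1))
    if exact is None:
        exact = min(n1, n2) <= 8 and not has_ties
    if exact and var > 0:
        if has_ties:
            flags.append("exact-with-ties-unavailable")
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            p = float(res.pvalue)
            flags.append("exact")
    return GroupComparisonResult(
        metric=metric,
        state=state,
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)) if n1 > 1 else 0.0,
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)) if n2 > 1 else 0.0,
        statistic_type="U",
        u=u1,
        z=float(z),
        p=float(min(p, 1.0)),
        n_x=n1,
        n_y=n2,
        flags=flags,
    )


def two_sample_z(x, y, metric: str = "", state: str = "") -> GroupComparisonResult:
    """Two-sample Z test on raw values or ``(mean, sd, n)`` summaries.

    ``Z = (mean_x - mean_y) / sqrt(sd_x^2 / n_x + sd_y^2 / n_y)``,
    two-sided p from the standard normal.
    """

    def summarise(v):
        if isinstance(v, tuple) and len(v) == 3:
            mean, sd, n = v
            if sd < 0:
                raise ValueError("sd must be >= 0")
            return float(mean), float(sd), int(n)
        arr = np.asarray(v, dtype=float)
        if arr.size < 2:
            raise ValueError("need n >= 2 per group")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    mx, sx, nx = summarise(x)
    my, sy, ny = summarise(y)
    if nx < 2 or ny < 2:
        raise ValueError("need n >= 2 per group")
    se = np.sqrt(sx**2 / nx + sy**2 / ny)
    flags: list[str] = []
    if se == 0:
        if mx == my:
            z, p = 0.0, 1.0
            flags.append("degenerate")
        else:
            z = np.inf if mx > my else -np.inf
            p = 0.0
            flags.append("infinite-z")
    else:
        z = (mx - my) / se
        p = 2 * sps.norm.sf(abs(z))
    return GroupComparisonResult(
        metric=metric,
        state=state,
        mean_x=mx,
        sd_x=sx,
        mean_y=my,
        sd_y=sy,
        statistic_type="Z",
        u=None,
        z=float(z),
        p=float(p),
        n_x=nx,
        n_y=ny,
        flags=flags,
    )


def _result_rows(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state": r.state,
                "metric": r.metric,
                "mean_a": r.mean_x,
                "sd_a": r.sd_x,
                "mean_b": r.mean_y,
                "sd_b": r.sd_y,
                "statistic": r.statistic_type,
                "U": r.u,
                "Z": r.z,
                "p": r.p,
                "n_a": r.n_x,
                "n_b": r.n_y,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


def compare_parameter_tables(
    params_a: pd.DataFrame,
    params_b: pd.DataFrame,
    metrics=("duration_ms", "occurrence_hz", "coverage"),
    correction: str | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney comparison per (state x metric) of two tidy tables.

    Tables carry columns ``subject, state, metric, value`` with matched
    state labels. No multiple-testing correction is applied by default;
    ``correction='holm'`` adds a ``p_holm`` column (documented deviation
    from reporting every test at its nominal level).
    """
    for df, name in [(params_a, "A"), (params_b, "B")]:
        missing = {"subject", "state", "metric", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"table {name} missing columns {sorted(missing)}")
    states_a = sorted(params_a["state"].unique())
    states_b = sorted(params_b["state"].unique())
    if states_a != states_b:
        raise ValueError(f"unmatched states: {states_a} vs {states_b}")
    results = []
    for state in states_a:
        for metric in metrics:
            xa = params_a.query("state == @state and metric == @metric")["value"]
            xb = params_b.query("state == @state and metric == @metric")["value"]
            if xa.empty or xb.empty:
                raise ValueError(f"no values for state {state} metric {metric}")
            results.append(
                mann_whitney(
                    xa.to_numpy(),
                    xb.to_numpy(),
                    metric=metric,
                    state=str(state),
                    exact=exact,
                )
            )
    out = _result_rows(results)
    if correction == "holm":
        out["p_holm"] = _holm(out["p"].to_numpy())
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_connectivity_tables(
    pooled_a: dict, pooled_b: dict
) -> pd.DataFrame:
    """Two-sample Z per microstate on pooled connectivity summaries.

    ``pooled_a`` / ``pooled_b`` map state label to a dict with keys
    ``mean``, ``sd``, ``n`` (as produced by ``summarize_connectivity``).
    The sign convention is first-group mean minus second-group mean.
    The pooled edge values are treated as independent observations; that
    simplification is recorded in the output flags.
    """
    if set(pooled_a) != set(pooled_b):
        raise ValueError("state sets differ between groups")
    results = []
    for state in sorted(pooled_a):
        a, b = pooled_a[state], pooled_b[state]
        for s, name in [(a, "first"), (b, "second")]:
            if "n" not in s or s["n"] is None:
                raise ValueError(
                    f"pooled summary for state {state} ({name} group) lacks n"
                )
        r = two_sample_z(
            (a["mean"], a["sd"], a["n"]),
            (b["mean"], b["sd"], b["n"]),
            metric="connectivity",
            state=str(state),
        )
        r.flags.append("edges-treated-as-independent")
        results.append(r)
    return _result_rows(results)


def percent_display(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding (clinical-table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) / Decimal(total) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(
    table: pd.DataFrame, integer_percent: tuple[str, ...] = ()
) -> dict:
    """Descriptive summary: mean +- SD for numeric columns, counts and
    percentages for categorical ones.

    Columns named in ``integer_percent`` display whole-number
    percentages (as some clinical tables do); all others use one
    decimal, half-up.
    """
    if table.empty:
        raise ValueError("attribute table is empty")
    out: dict = {"n": int(len(table))}
    for col in table.columns:
        series = table[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = {
                "mean": float(series.mean()),
                "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
            }
        else:
            decimals = 0 if col in integer_percent else 1
            counts = series.value_counts()
            out[col] = {
                str(val): {
                    "count": int(cnt),
                    "percent": percent_display(int(cnt), len(table), decimals),
                }
                for val, cnt in counts.items()
            }
    return out
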