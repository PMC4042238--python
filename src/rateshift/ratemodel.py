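"""Reference-normalized substitution-rate-change model.

The locus is compared against concatenated exons of flanking genes on the
fixed four-species tree (((mouse, rat), human), dog).  Three stage rates
describe the test region — r0 before an inversion, r1 between the
inversion and the birth of the lncRNA pair, r2 afterwards — while the
reference evolves at a single rate rR.  With k1 the fraction of the
human–rodent divergence time elapsed since the inversion could last have
occurred, and k2 the analogous fraction of the mouse–rat time for gene
birth, the expected pairwise distances are

    d_test_HD = 2 r0 t_HD
    d_test_HR = (1+k1) r0 t_HR + (1-k1) r1 t_HR
    d_test_MR = (1+k2) r1 t_MR + (1-k2) r2 t_MR
    d_ref_XY  = 2 rR t_XY

so the normalized average rates (test distance / reference distance) are

    r_averHD = rho0
    r_averHR = [(1+k1) rho0 + (1-k1) rho1] / 2
    r_averMR = [(1+k2) rho1 + (1-k2) rho2] / 2

with rho_i = r_i / rR.  The divisor 2 in the HR and MR expressions is
required for algebraic consistency (it is what division by d_ref gives,
and it makes r_averHR -> r_averHD as k1 -> 1 when rates do not change);
the uncorrected "printed" form without the divisor is available for
comparison via ``printed_form=True``.

Given measured normalized rates the three rho's are recovered exactly
for any assumed (k1, k2); since the event times are only known to lie in
an interval, ``rate_ratio_scan`` tabulates the solution over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .alignments import FilterPolicy, MultipleAlignment, concat_alignments, filter_columns
from .distances import DistanceEstimate, pairwise_distance

Effect = Literal["reduced", "increased", "unchanged"]

#: Species pairs entering the model, in (HD, HR, MR) order.
PAIRS = (("human", "dog"), ("human", "rat"), ("mouse", "rat"))


@dataclass(frozen=True)
class NormalizedRates:
    """The three normalized average rates (dimensionless, all > 0)."""

    r_aver_hd: float
    r_aver_hr: float
    r_aver_mr: float

    def __post_init__(self) -> None:
        if min(self.r_aver_hd, self.r_aver_hr, self.r_aver_mr) <= 0:
            raise ValueError("normalized rates must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r_aver_hd, self.r_aver_hr, self.r_aver_mr)


@dataclass(frozen=True)
class RateShiftCall:
    inversion_effect: Effect
    birth_effect: Effect
    tolerance: float


@dataclass(frozen=True)
class RateRatioSolution:
    rho0: float
    rho1: float
    rho2: float
    k1: float
    k2: float
    feasible: bool  # all rho > 0


def forward_rates(
    rho0: float,
    rho1: float,
    rho2: float,
    k1: float,
    k2: float,
    printed_form: bool = False,
) -> NormalizedRates:
    """Expected normalized rates for stage-rate ratios rho_i = r_i/rR."""
    _check_k(k1, k2)
    div = 1.0 if printed_form else 2.0
    return NormalizedRates(
        rho0,
        ((1 + k1) * rho0 + (1 - k1) * rho1) / div,
        ((1 + k2) * rho1 + (1 - k2) * rho2) / div,
    )


def normalized_rates(
    d_test_hd: DistanceEstimate | float,
    d_test_hr: DistanceEstimate | float,
    d_test_mr: DistanceEstimate | float,
    d_ref_hd: DistanceEstimate | float,
    d_ref_hr: DistanceEstimate | float,
    d_ref_mr: DistanceEstimate | float,
) -> NormalizedRates:
    """Test/reference distance ratios per species pair."""
    test = [_value(d) for d in (d_test_hd, d_test_hr, d_test_mr)]
    ref = [_value(d) for d in (d_ref_hd, d_ref_hr, d_ref_mr)]
    for name, r in zip(("HD", "HR", "MR"), ref):
        if r <= 0:
            raise ValueError(f"reference distance {name} is zero: reference uninformative")
    return NormalizedRates(*(t / r for t, r in zip(test, ref)))


def infer_ordering(nr: NormalizedRates, tolerance: float = 0.02) -> RateShiftCall:
    """Qualitative direction of the two rate changes.

    The inversion comparison is r_averHD vs r_averHR (r_averHR below the
    tolerance band around r_averHD implies r1 < r0, i.e. the rate was
    reduced after the inversion); gene birth is read off r_averMR
    relative to r_averHR the same way, since the mouse–rat path is the
    only one the post-birth rate touches.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return RateShiftCall(
        inversion_effect=_direction(nr.r_aver_hr, nr.r_aver_hd, tolerance),
        birth_effect=_direction(nr.r_aver_mr, nr.r_aver_hr, tolerance),
        tolerance=tolerance,
    )


def solve_rate_ratios(
    nr: NormalizedRates, k1: float, k2: float, printed_form: bool = False
) -> RateRatioSolution:
    """Invert the forward model at an assumed (k1, k2).

    rho0 = r_averHD;
    rho1 = (2 r_averHR - (1+k1) rho0) / (1-k1);
    rho2 = (2 r_averMR - (1+k2) rho1) / (1-k2).
    A solution with any rho <= 0 is flagged infeasible (the measured
    ratios cannot arise from positive stage rates at that timing).
    """
    _check_k(k1, k2)
    mul = 1.0 if printed_form else 2.0
    rho0 = nr.r_aver_hd
    rho1 = (mul * nr.r_aver_hr - (1 + k1) * rho0) / (1 - k1)
    rho2 = (mul * nr.r_aver_mr - (1 + k2) * rho1) / (1 - k2)
    feasible = rho0 > 0 and rho1 > 0 and rho2 > 0
    return RateRatioSolution(rho0, rho1, rho2, k1, k2, feasible)


def rate_ratio_scan(
    nr: NormalizedRates, grid_step: float = 0.05, printed_form: bool = False
) -> "ScanResult":
    """Solve the model over a (k1, k2) grid in the open unit square."""
    if not 0 < grid_step < 1:
        raise ValueError("grid_step must lie in (0, 1)")
    n = int(round(1.0 / grid_step))
    ks = [i * grid_step for i in range(1, n) if i * grid_step < 1.0 - 1e-12]
    rows = []
    for k1 in ks:
        for k2 in ks:
            s = solve_rate_ratios(nr, k1, k2, printed_form=printed_form)
            rows.append((k1, k2, s.rho0, s.rho1, s.rho2, s.feasible))
    table = pd.DataFrame(rows, columns=["k1", "k2", "rho0", "rho1", "rho2", "feasible"])
    feas = table[table["feasible"]]
    summary = {
        "n_grid": len(table),
        "n_feasible": int(len(feas)),
        "rho_ranges": {
            col: (float(feas[col].min()), float(feas[col].max())) if len(feas) else (np.nan, np.nan)
            for col in ("rho0", "rho1", "rho2")
        },
    }
    return ScanResult(table=table, summary=summary)


@dataclass
class ScanResult:
    table: pd.DataFrame
    summary: dict

    def at(self, k1: float, k2: float) -> RateRatioSolution:
        t = self.table
        hit = t[(np.isclose(t.k1, k1)) & (np.isclose(t.k2, k2))]
        if hit.empty:
            raise KeyError(f"({k1}, {k2}) not on the scan grid")
        r = hit.iloc[0]
        return RateRatioSolution(r.rho0, r.rho1, r.rho2, r.k1, r.k2, bool(r.feasible))


@dataclass
class RateReport:
    """All intermediates of one rate-change analysis."""

    model: str
    policy: FilterPolicy
    test_columns_used: int
    ref_columns_used: int
    distances_test: dict[str, float]
    distances_ref: dict[str, float]
    sites: dict[str, int]
    normalized: NormalizedRates
    call: RateShiftCall
    scan: ScanResult
    printed_form_normalized: NormalizedRates | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "filter_policy": {
                "drop_gap_columns": self.policy.drop_gap_columns,
                "window_len": self.policy.window_len,
                "min_window_identity": self.policy.min_window_identity,
            },
            "test_columns_used": self.test_columns_used,
            "ref_columns_used": self.ref_columns_used,
            "distances_test": self.distances_test,
            "distances_ref": self.distances_ref,
            "sites_used": self.sites,
            "normalized_rates": {
                "r_aver_hd": self.normalized.r_aver_hd,
                "r_aver_hr": self.normalized.r_aver_hr,
                "r_aver_mr": self.normalized.r_aver_mr,
            },
            "call": {
                "inversion_effect": self.call.inversion_effect,
                "birth_effect": self.call.birth_effect,
                "tolerance": self.call.tolerance,
            },
            "scan_summary": self.scan.summary,
        }
        return d


def run_rate_analysis(
    test_aln: MultipleAlignment,
    ref_alns: Sequence[MultipleAlignment],
    policy: FilterPolicy | None = None,
    model: str = "k80",
    tolerance: float = 0.02,
    grid_step: float = 0.05,
) -> RateReport:
    """Full pipeline: filter -> concatenate references -> distances ->
    normalized rates -> ordering call + (k1, k2) scan."""
    policy = policy or FilterPolicy()
    required = {sp for pair in PAIRS for sp in pair}
    for stage, aln in [("test", test_aln)] + [("reference", a) for a in ref_alns]:
        missing = required - set(aln.rows)
        if missing:
            raise ValueError(f"{stage} alignment missing species {sorted(missing)}")

    try:
        test = filter_columns(test_aln, policy)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"column filtering of test alignment failed: {exc}") from exc
    refs = [filter_columns(a, policy) for a in ref_alns]
    ref = concat_alignments(refs)

    def pair_dist(aln: MultipleAlignment, a: str, b: str) -> DistanceEstimate:
        try:
            return pairwise_distance(aln.rows[a], aln.rows[b], model)
        except ValueError as exc:
            raise ValueError(f"distance estimation failed for ({a}, {b}): {exc}") from exc

    d_test = {f"{a[0].upper()}{b[0].upper()}": pair_dist(test, a, b) for a, b in PAIRS}
    d_ref = {f"{a[0].upper()}{b[0].upper()}": pair_dist(ref, a, b) for a, b in PAIRS}

    nr = normalized_rates(
        d_test["HD"], d_test["HR"], d_test["MR"],
        d_ref["HD"], d_ref["HR"], d_ref["MR"],
    )
    call = infer_ordering(nr, tolerance)
    scan = rate_ratio_scan(nr, grid_step)
    return RateReport(
        model=model,
        policy=policy,
        test_columns_used=test.n_columns,
        ref_columns_used=ref.n_columns,
        distances_test={k: v.value for k, v in d_test.items()},
        distances_ref={k: v.value for k, v in d_ref.items()},
        sites={f"test_{k}": v.sites_used for k, v in d_test.items()}
        | {f"ref_{k}": v.sites_used for k, v in d_ref.items()},
        normalized=nr,
        call=call,
        scan=scan,
    )


def _value(d: DistanceEstimate | float) -> float:
    return d.value if isinstance(d, DistanceEstimate) else float(d)


def _direction(later: float, earlier: float, tol: float) -> Effect:
    if later < earlier * (1 - tol):
        return "reduced"
    if later > earlier * (1 + tol):
        return "increased"
    return "unchanged"


def _check_k(k1: float, k2: float) -> None:
    for name, k in (("k1", k1), ("k2", k2)):
        if not 0 < k < 1:
            raise ValueError(f"{name} must lie strictly in (0, 1); got {k}")
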