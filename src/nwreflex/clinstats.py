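"""Nonparametric statistical battery and clinical classification rules.

The battery mirrors what a clinical neurophysiology cohort study runs on
responder/response-rate, latency, reflex-magnitude and pain data:

* Wilcoxon rank-sum (Mann-Whitney) for group comparisons, effect size
  r = |Z| / sqrt(N) (r < 0.3 small, < 0.5 medium, > 0.5 large);
* Fisher's exact test with the phi coefficient for 2x2 associations;
* Kendall's tau-b for rank correlations with ties;
* the eta coefficient, sqrt(SS_between / SS_total), for binary-vs-metric
  association (p via the equivalent one-way ANOVA F-test).

A priori one-tailed tests are used for the directional hyperreflexia
hypotheses (responders / response rates SCI > NDC, spasticity-reflex
correlations); everything else is two-tailed. Missing data are removed
pairwise per test and each result reports its own n. No multiple-testing
correction is applied; the report carries the number of tests run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .signal_io import ParticipantRecord

ALPHA = 0.05
EXACT_MAX_N = 12  # exact rank-sum enumeration up to this combined n


@dataclass
class StatResult:
    method: str         # wilcoxon_rank_sum | fisher_exact | kendall_tau_b | eta
    statistic: float
    p_value: float
    tails: str          # one | two
    effect_size: float | None
    effect_kind: str    # r | phi | tau_b | eta | none
    n: int
    note: str = ""


@dataclass
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(W, z, var) for the rank-sum of x with midrank ties, continuity- and
    tie-corrected normal approximation."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 0.0, 0.0
    diff = w - mu
    cc = 0.5 if abs(diff) > 0.5 else 0.0  # continuity correction
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
    return w, z, var


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray,
                      alternative: str) -> float:
    """Exact p by enumerating all C(n, n1) group assignments (handles ties)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(idx)].sum()
                     for idx in combinations(range(len(pooled)), n1)])
    eps = 1e-9
    p_ge = float((sums >= w_obs - eps).mean())
    p_le = float((sums <= w_obs + eps).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_rank_sum(x, y, tails: str = "two",
                      alternative: str = "greater") -> StatResult:
    """Rank-sum comparison of two independent samples.

    ``tails="one"`` tests the directional alternative that ``x`` tends to be
    ``alternative`` ("greater"/"less") than ``y``. Exact enumeration is used
    for combined n <= 12, otherwise the tie/continuity-corrected normal
    approximation. Effect size r = |Z| / sqrt(n1 + n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n = len(x) + len(y)
    w, z, var = _rank_sum_z(x, y)
    if var == 0.0:  # all pooled values identical
        return StatResult("wilcoxon_rank_sum", w, 1.0, tails, 0.0, "r", n,
                          note="degenerate: no variation")
    alt = alternative if tails == "one" else "two-sided"
    if n <= EXACT_MAX_N:
        p = _rank_sum_exact_p(x, y, alt)
        note = "exact enumeration"
    else:
        if alt == "greater":
            p = float(sstats.norm.sf(z))
        elif alt == "less":
            p = float(sstats.norm.cdf(z))
        else:
            p = float(2.0 * sstats.norm.sf(abs(z)))
        note = "normal approximation"
    p = min(1.0, max(p, np.finfo(float).tiny))
    r = abs(z) / math.sqrt(n)
    return StatResult("wilcoxon_rank_sum", w, p, tails, r, "r", n, note=note)


# --------------------------------------------------------------------------
# Fisher's exact test and phi
# --------------------------------------------------------------------------

def fisher_exact_2x2(t: Contingency2x2, tails: str = "two",
                     alternative: str = "greater") -> StatResult:
    """Fisher's exact test on a 2x2 table; effect size phi.

    Two-tailed p sums all hypergeometric tables no more probable than the
    observed one; one-tailed p is the tail in the stated direction of the
    odds ratio.
    """
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        raise ValueError("Fisher test needs all margins positive")
    alt = {"one": alternative, "two": "two-sided"}[tails]
    odds, p = sstats.fisher_exact(t.table, alternative=alt)
    n = t.a + t.b + t.c + t.d
    return StatResult("fisher_exact", float(odds), float(p), tails,
                      phi_coefficient(t), "phi", n)


def phi_coefficient(t: Contingency2x2) -> float:
    """|ad - bc| / sqrt of the product of margins (reported as magnitude)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        raise ValueError("phi undefined with an empty margin")
    return abs(a * d - b * c) / denom


def hypergeom_enumeration_p(t: Contingency2x2) -> float:
    """Brute-force two-tailed Fisher p: enumerate every table with the same
    margins and sum probabilities <= the observed table's probability."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    rv = sstats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(t.a)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        pa = rv.pmf(a)
        if pa <= p_obs * (1 + 1e-9):
            total += pa
    return float(min(1.0, total))


# --------------------------------------------------------------------------
# Kendall tau-b
# --------------------------------------------------------------------------

def kendall_tau_b(x, y, tails: str = "two",
                  alternative: str = "greater") -> StatResult:
    """Kendall rank correlation with tie correction (tau-b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("tau-b needs n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult("kendall_tau_b", float("nan"), 1.0, tails, None,
                          "none", len(x), note="degenerate: zero variance")
    res = sstats.kendalltau(x, y, variant="b")
    tau, p2 = float(res.statistic), float(res.pvalue)
    if tails == "one":
        if (alternative == "greater") == (tau >= 0):
            p = p2 / 2.0
        else:
            p = 1.0 - p2 / 2.0
    else:
        p = p2
    return StatResult("kendall_tau_b", tau, p, tails, tau, "tau_b", len(x))


def kendall_tau_b_bruteforce(x, y) -> float:
    """O(n^2) pair-counting oracle for tau-b (used by the test suite)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_pairs(x)) * (n0 - _tie_pairs(y)))
    return (conc - disc) / denom if denom else float("nan")


def _tie_pairs(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


# --------------------------------------------------------------------------
# eta coefficient
# --------------------------------------------------------------------------

def eta_coefficient(groups, y) -> float:
    """eta = sqrt(SS_between / SS_total) for a binary grouping of a metric
    variable; pairwise-complete."""
    g = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    g, y = g[keep], y[keep]
    levels = np.unique(g)
    if any((g == lev).sum() == 0 for lev in levels) or len(levels) < 2:
        raise ValueError("both groups must be non-empty")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("eta undefined: SS_total = 0")
    ss_between = sum(float((g == lev).sum()) * (y[g == lev].mean() - y.mean()) ** 2
                     for lev in levels)
    return math.sqrt(ss_between / ss_total)


def eta_test(groups, y) -> StatResult:
    """eta with a p-value from the equivalent one-way ANOVA F-test."""
    g = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    g, y = g[keep], y[keep]
    eta = eta_coefficient(g, y)
    samples = [y[g == lev] for lev in np.unique(g)]
    if all(len(s) > 1 for s in samples) and eta < 1.0:
        f, p = sstats.f_oneway(*samples)
        p = float(p)
    else:
        p = 0.0 if eta == 1.0 else 1.0
    return StatResult("eta", eta, p, "two", eta, "eta", len(y))


# --------------------------------------------------------------------------
# clinical classification
# --------------------------------------------------------------------------

@dataclass
class ClinicalFlags:
    spasticity_relevant: bool | None
    scipi_positive: bool | None
    nrs_relevant: bool | None


def classify_clinical(record: ParticipantRecord) -> ClinicalFlags:
    """Clinically relevant spasticity (> grade 1 in any joint for MAS or
    SCAT), positive neuropathic-pain screen (SCIPI >= 4/7) and clinically
    relevant spontaneous pain (NRS >= 4).

    When only score means are available, relevance falls back to
    mean > 1; with a mean <= 1 the any-joint maximum is unknowable from the
    mean alone, but a mean of exactly 0 does imply no joint above 1.
    """
    if record.MAS_joint_scores or record.SCAT_joint_scores:
        spast = (any(s > 1 for s in record.MAS_joint_scores)
                 or any(s > 1 for s in record.SCAT_joint_scores))
    elif record.MAS_mean is None and record.SCAT_mean is None:
        spast = None
    else:
        vals = [v for v in (record.MAS_mean, record.SCAT_mean) if v is not None]
        spast = any(v > 1 for v in vals)
    scipi = None if record.SCIPI_score is None else record.SCIPI_score >= 4
    nrs = None if record.NRS_spontaneous is None else record.NRS_spontaneous >= 4
    return ClinicalFlags(spast, scipi, nrs)


def spasticity_pain_table(records: list[ParticipantRecord]) -> Contingency2x2:
    """CPG (rows: yes/no) x clinically relevant spasticity (cols: yes/no)."""
    a = b = c = d = 0
    for r in records:
        if r.CPG_neuropathic is None:
            continue
        flags = classify_clinical(r)
        if flags.spasticity_relevant is None:
            continue
        if r.CPG_neuropathic:
            a += flags.spasticity_relevant
            b += not flags.spasticity_relevant
        else:
            c += flags.spasticity_relevant
            d += not flags.spasticity_relevant
    return Contingency2x2(a, b, c, d)


# --------------------------------------------------------------------------
# the battery
# --------------------------------------------------------------------------

def _result_row(analysis: str, res: StatResult | None, site: str = "",
                extra_note: str = "") -> dict:
    row = {"analysis": analysis, "site": site}
    if res is None:
        row.update({"method": "", "statistic": np.nan, "p_value": np.nan,
                    "tails": "", "effect_size": np.nan, "effect_kind": "none",
                    "n": 0, "note": extra_note or "insufficient data"})
    else:
        row.update({"method": res.method, "statistic": res.statistic,
                    "p_value": res.p_value, "tails": res.tails,
                    "effect_size": (np.nan if res.effect_size is None
                                    else res.effect_size),
                    "effect_kind": res.effect_kind, "n": res.n,
                    "note": "; ".join(filter(None, (res.note, extra_note)))})
    return row


def run_battery(summaries: pd.DataFrame | None,
                records: list[ParticipantRecord]) -> pd.DataFrame:
    """Run the full analysis set and return one row per test.

    ``summaries`` is the per-participant response-summary table (or None for
    a clinical-only analysis). Tests that cannot run (insufficient data)
    yield flagged rows rather than disappearing.
    """
    rows: list[dict] = []
    rec_by_id = {r.participant_id: r for r in records}
    sci_ids = [r.participant_id for r in records if r.group == "SCI"]
    ndc_ids = [r.participant_id for r in records if r.group == "NDC"]

    if summaries is not None and len(summaries):
        s = summaries
        for site in sorted(s.site.unique()):
            tw2 = s[(s.site == site) & (s.window == "TW2")]
            x = tw2[tw2.participant_id.isin(sci_ids)].response_rate_pct.dropna()
            y = tw2[tw2.participant_id.isin(ndc_ids)].response_rate_pct.dropna()
            res = None
            if len(x) and len(y):
                res = wilcoxon_rank_sum(x, y, tails="one", alternative="greater")
            rows.append(_result_row("response_rate_TW2_SCI_vs_NDC", res, site))

            # latency and magnitude comparisons (two-tailed, per muscle is
            # folded into the per-trial-earliest convention of the summary)
            for col, name in (("latency_mean_ms", "latency_TW2_SCI_vs_NDC"),
                              ("auc_mean_uVs", "auc_TW2_SCI_vs_NDC")):
                x = tw2[tw2.participant_id.isin(sci_ids)][col].dropna()
                y = tw2[tw2.participant_id.isin(ndc_ids)][col].dropna()
                res = (wilcoxon_rank_sum(x, y, tails="two")
                       if len(x) and len(y) else None)
                rows.append(_result_row(name, res, site))

            any_rows = s[(s.site == site) & (s.window == "any")]
            x = any_rows[any_rows.participant_id.isin(sci_ids)] \
                .pain_rating_mean.dropna()
            y = any_rows[any_rows.participant_id.isin(ndc_ids)] \
                .pain_rating_mean.dropna()
            res = (wilcoxon_rank_sum(x, y, tails="two")
                   if len(x) and len(y) else None)
            rows.append(_result_row("pain_rating_SCI_vs_NDC", res, site))

        # responders TW2, any site: SCI vs NDC (one-tailed Fisher)
        resp = {}
        for pid in sci_ids + ndc_ids:
            sub = s[(s.participant_id == pid) & (s.window == "TW2")]
            resp[pid] = bool(sub.responder.any()) if len(sub) else None
        a = sum(1 for p in sci_ids if resp.get(p))
        b = sum(1 for p in sci_ids if resp.get(p) is False)
        c = sum(1 for p in ndc_ids if resp.get(p))
        d = sum(1 for p in ndc_ids if resp.get(p) is False)
        res = None
        if (a + b) and (c + d) and (a + c) and (b + d):
            res = fisher_exact_2x2(Contingency2x2(a, b, c, d), tails="one",
                                   alternative="greater")
        rows.append(_result_row("responders_TW2_SCI_vs_NDC", res,
                                extra_note=f"SCI {a}/{a + b}, NDC {c}/{c + d}"))

        # spasticity / pain vs response rates, SCI only
        for site in sorted(s.site.unique()):
            tw2 = s[(s.site == site) & (s.window == "TW2")
                    & s.participant_id.isin(sci_ids)]
            rates, mas, scat, nrs, cpg = [], [], [], [], []
            for _, row in tw2.iterrows():
                rec = rec_by_id[row.participant_id]
                rates.append(row.response_rate_pct)
                mas.append(np.nan if rec.MAS_mean is None else rec.MAS_mean)
                scat.append(np.nan if rec.SCAT_mean is None else rec.SCAT_mean)
                nrs.append(np.nan if rec.NRS_spontaneous is None
                           else rec.NRS_spontaneous)
                cpg.append(np.nan if rec.CPG_neuropathic is None
                           else float(rec.CPG_neuropathic))
            rates = np.asarray(rates, dtype=float)

            def tau_row(name, v, tails, alternative="greater"):
                v = np.asarray(v, dtype=float)
                keep = ~(np.isnan(rates) | np.isnan(v))
                res = None
                if keep.sum() >= 3 and np.ptp(rates[keep]) > 0 \
                        and np.ptp(v[keep]) > 0:
                    res = kendall_tau_b(rates[keep], v[keep], tails=tails,
                                        alternative=alternative)
                rows.append(_result_row(name, res, site))

            tau_row("tau_rate_TW2_vs_MAS", mas, "one")
            tau_row("tau_rate_TW2_vs_SCAT", scat, "one")
            tau_row("tau_rate_TW2_vs_NRS", nrs, "two")

            cpg_arr = np.asarray(cpg, dtype=float)
            keep = ~(np.isnan(rates) | np.isnan(cpg_arr))
            res = None
            if keep.sum() >= 3 and len(np.unique(cpg_arr[keep])) == 2 \
                    and np.ptp(rates[keep]) > 0:
                res = eta_test(cpg_arr[keep], rates[keep])
            rows.append(_result_row("eta_CPG_vs_rate_TW2", res, site))

    # clinical-only analyses (always run)
    sci_recs = [r for r in records if r.group == "SCI"]
    for score, name in (("MAS_mean", "eta_CPG_vs_MAS"),
                        ("SCAT_mean", "eta_CPG_vs_SCAT")):
        pairs = [(float(r.CPG_neuropathic), getattr(r, score))
                 for r in sci_recs
                 if r.CPG_neuropathic is not None and getattr(r, score) is not None]
        res = None
        if len(pairs) >= 3 and len({g for g, _ in pairs}) == 2:
            g, v = zip(*pairs)
            if np.ptp(v) > 0:
                res = eta_test(np.array(g), np.array(v))
        rows.append(_result_row(name, res))

    try:
        tab = spasticity_pain_table(sci_recs)
        res = fisher_exact_2x2(tab, tails="two")
        rows.append(_result_row(
            "fisher_CPG_vs_spasticity", res,
            extra_note=f"table a={tab.a} b={tab.b} c={tab.c} d={tab.d}"))
    except ValueError as exc:
        rows.append(_result_row("fisher_CPG_vs_spasticity", None,
                                extra_note=str(exc)))

    df = pd.DataFrame(rows)
    df.attrs["n_tests"] = int(df.method.astype(bool).sum())
    return df


def battery_report(df: pd.DataFrame) -> str:
    """Human-readable key-value rendering of the battery output."""
    lines = [f"statistical battery: {df.attrs.get('n_tests', len(df))} tests "
             f"(no multiple-testing correction; alpha = {ALPHA})"]
    for _, r in df.iterrows():
        site = f" [{r.site}]" if r.site else ""
        if not r.method:
            lines.append(f"{r.analysis}{site}: not testable ({r.note})")
            continue
        eff = ("" if pd.isna(r.effect_size)
               else f", {r.effect_kind} = {r.effect_size:.2f}")
        star = " *" if r.p_value <= ALPHA else ""
        lines.append(f"{r.analysis}{site}: {r.method} ({r.tails}-tailed) "
                     f"p = {r.p_value:.3g}{eff}, n = {r.n}{star}")
    return "\n".join(lines)
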