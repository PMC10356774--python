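"""Seeded simulator of visit-level claims tables with planted risk structure.

Real statewide discharge datasets (the setting this package targets) are
access-restricted, so the package ships a generative stand-in: multi-visit
patient trajectories with irregular inter-visit gaps, ICD-like diagnosis
codes organised into clinical categories, procedure-category codes,
demographic strata, and a rare binary outcome whose hazard is driven by
planted risk-code exposures.

The generative model:

* Visit timing — per-patient homogeneous Poisson process over the simulated
  date range (visit count ~ Poisson(visit_rate) truncated at one visit, visit
  days uniform order statistics), producing irregular gaps that span all
  seven temporal buckets used downstream.
* Disease dynamics — a sticky first-order Markov chain over diagnosis
  categories across consecutive visits; the principal diagnosis is drawn
  within the visit's category. A latent high-risk patient class up-weights
  psychiatric / substance-use / injury / homelessness categories, creating
  the exposure heterogeneity the outcome model feeds on.
* Outcome mechanics — a discrete-time logistic hazard over twelve ~30-day
  post-index intervals whose logit increases by ``risk_effect`` per planted
  risk-code exposure accrued up to the index visit, plus small age/sex
  effects. The intercept is calibrated by root finding so the expected
  outcome prevalence matches ``outcome_prevalence_target``.

Identical configurations (including seed) yield byte-identical tables.
"""

from __future__ import annotations

import datetime as _dt
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimConfig",
    "CategoryMap",
    "default_category_map",
    "simulate_cohort",
    "summarize_cohort",
    "CohortSummary",
    "VISIT_COLUMNS",
]

VISIT_COLUMNS = [
    "patient_id",
    "visit_date",
    "principal_dx",
    "aux_dx",
    "ecause",
    "procedures",
    "facility_id",
    "age_decade",
    "sex",
    "race",
    "payor",
]

#: Named predictor groups planted by the default category map.
RISK_GROUPS = ("psychiatric", "substance_use", "injury", "pregnancy", "homelessness")
OUTCOME_GROUP = "outcome"

# Demographic marginals, loosely matching a statewide adult ED/inpatient mix.
AGE_DECADES = [str(d) for d in range(9)]  # 0 => 0-9 years, 8 => 80+
AGE_WEIGHTS = [0.08, 0.08, 0.12, 0.12, 0.14, 0.14, 0.12, 0.11, 0.09]
SEXES = ["F", "M"]
SEX_WEIGHTS = [0.59, 0.41]
RACES = ["White", "Black", "Hispanic", "Asian", "Native", "Other"]
RACE_WEIGHTS = [0.43, 0.13, 0.36, 0.06, 0.01, 0.01]
PAYORS = ["Medicare", "Medicaid", "Private", "Self", "Other"]
PAYOR_WEIGHTS = [0.32, 0.40, 0.21, 0.04, 0.03]

_N_HAZARD_BUCKETS = 12  # ~30-day discrete-hazard intervals covering 365 days


def make_dx_vocabulary(n_codes: int) -> list[str]:
    """ICD-like three-character diagnosis codes: a letter plus two digits."""
    if n_codes <= 0:
        raise ValueError("vocabulary must be non-empty")
    if n_codes > 2600:
        raise ValueError("at most 2600 three-character codes are available")
    letters = string.ascii_uppercase
    return [f"{letters[i // 100]}{i % 100:02d}" for i in range(n_codes)]


def make_proc_vocabulary(n_codes: int) -> list[str]:
    """Procedure-category codes in the style of CCS service groupings."""
    return [f"PR{i:03d}" for i in range(n_codes)]


@dataclass(frozen=True)
class CategoryMap:
    """Total mapping from diagnosis codes to clinical categories.

    Stands in for a CCSR-style grouper. ``groups`` names the planted
    predictor categories and the outcome category; the outcome group is
    disjoint from every predictor group.
    """

    code_to_category: dict[str, str]
    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        outcome = self.groups.get(OUTCOME_GROUP, frozenset())
        for name, codes in self.groups.items():
            if name != OUTCOME_GROUP and outcome & codes:
                raise ValueError(f"outcome group overlaps predictor group {name!r}")

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.code_to_category.values()))

    @property
    def outcome_codes(self) -> frozenset[str]:
        return self.groups[OUTCOME_GROUP]

    def category_of(self, code: str) -> str:
        return self.code_to_category[code]


def default_category_map(dx_codes: list[str], n_categories: int = 12) -> CategoryMap:
    """Partition the diagnosis vocabulary into named and neutral categories.

    The first six categories are the named groups (five predictor groups plus
    the outcome group); remaining codes are spread over ``n_categories - 6``
    neutral categories. The outcome group is kept deliberately small (about
    2% of the vocabulary) so outcome codes are rare by construction.
    """
    if n_categories < 7:
        raise ValueError("need at least 7 categories (5 risk + outcome + neutral)")
    n = len(dx_codes)
    n_outcome = max(2, n // 50)
    n_named = max(3, n // 15)  # per predictor group
    names: list[str] = []
    code_to_cat: dict[str, str] = {}
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        chunk = dx_codes[cursor : cursor + k]
        cursor += k
        return chunk

    groups: dict[str, frozenset[str]] = {}
    groups[OUTCOME_GROUP] = frozenset(take(n_outcome))
    for g in RISK_GROUPS:
        groups[g] = frozenset(take(n_named))
    for name, codes in groups.items():
        for c in codes:
            code_to_cat[c] = name
    remaining = dx_codes[cursor:]
    n_neutral = n_categories - 6
    for i, c in enumerate(remaining):
        name = f"neutral_{i % n_neutral}"
        code_to_cat[c] = name
        names.append(name)
    for i in range(n_neutral):
        name = f"neutral_{i}"
        groups[name] = frozenset(c for c, g in code_to_cat.items() if g == name)
    return CategoryMap(code_to_category=code_to_cat, groups=groups)


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    ``risk_effect`` is the log-hazard increment per planted risk-code
    exposure accrued before the index visit; ``visit_rate`` is the mean
    number of visits per patient over the whole date range.
    """

    n_patients: int
    start_date: _dt.date = _dt.date(2016, 1, 1)
    end_date: _dt.date = _dt.date(2019, 12, 31)
    index_year: int = 2018
    n_dx_codes: int = 300
    n_proc_codes: int = 50
    n_categories: int = 12
    outcome_prevalence_target: float = 0.01
    risk_code_ids: frozenset[int] | None = None
    risk_effect: float = 1.0
    visit_rate: float = 5.5
    seed: int = 0
    prior_outcome_rate: float = 0.003
    high_risk_fraction: float = 0.10
    strata_effects: float = 1.0  # scales the age/sex hazard contributions

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if not (self.start_date.year <= self.index_year <= self.end_date.year):
            raise ValueError("index_year must lie within the date range")
        if not (0.0 < self.outcome_prevalence_target < 0.5):
            raise ValueError("outcome_prevalence_target must be in (0, 0.5)")
        if self.n_dx_codes <= 0:
            raise ValueError("vocabulary must be non-empty")
        if self.risk_code_ids is not None and any(
            i < 0 or i >= self.n_dx_codes for i in self.risk_code_ids
        ):
            raise ValueError("risk_code_ids must index the diagnosis vocabulary")


def _default_risk_code_ids(cmap: CategoryMap, dx_codes: list[str]) -> frozenset[int]:
    """Planted risk codes: the psychiatric, substance-use, and injury groups."""
    idx = {c: i for i, c in enumerate(dx_codes)}
    codes: set[int] = set()
    for g in ("psychiatric", "substance_use", "injury"):
        codes.update(idx[c] for c in cmap.groups[g])
    return frozenset(codes)


def simulate_cohort(
    config: SimConfig, category_map: CategoryMap | None = None
) -> pd.DataFrame:
    """Generate a visit-level claims table with planted risk structure.

    Returns one row per visit with the columns in :data:`VISIT_COLUMNS`.
    Dates are ISO-8601 strings; multi-code fields are ``;``-joined. Visits
    are sorted by (patient, date); demographics are constant per patient.
    """
    dx_codes = make_dx_vocabulary(config.n_dx_codes)
    proc_codes = make_proc_vocabulary(config.n_proc_codes)
    if category_map is None:
        category_map = default_category_map(dx_codes, config.n_categories)
    cmap = category_map
    if config.n_patients == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in VISIT_COLUMNS})

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cats = cmap.categories
    cat_idx = {c: i for i, c in enumerate(cats)}
    k_cat = len(cats)
    dx_arr = np.asarray(dx_codes, dtype=object)
    cat_of_code = np.asarray([cat_idx[cmap.category_of(c)] for c in dx_codes])
    codes_by_cat = [np.flatnonzero(cat_of_code == k) for k in range(k_cat)]
    outcome_cat = cat_idx[OUTCOME_GROUP]
    injury_cat = cat_idx.get("injury", -1)
    outcome_code_ids = codes_by_cat[outcome_cat]

    risk_ids = config.risk_code_ids
    if risk_ids is None:
        risk_ids = _default_risk_code_ids(cmap, dx_codes)
    is_risk_code = np.zeros(len(dx_codes), dtype=bool)
    is_risk_code[list(risk_ids)] = True

    # --- demographics (constant per patient) -------------------------------
    age = rng.choice(len(AGE_DECADES), size=n, p=AGE_WEIGHTS)
    sex = rng.choice(len(SEXES), size=n, p=SEX_WEIGHTS)
    race = rng.choice(len(RACES), size=n, p=RACE_WEIGHTS)
    payor = rng.choice(len(PAYORS), size=n, p=PAYOR_WEIGHTS)
    high_risk = rng.random(n) < config.high_risk_fraction

    # category preference weights: base patients favour neutral categories,
    # high-risk patients put extra mass on the planted predictor groups
    base_w = np.ones(k_cat)
    base_w[outcome_cat] = 0.0  # outcome codes never arise from the chain
    for g in RISK_GROUPS:
        if g in cat_idx:
            base_w[cat_idx[g]] = 0.5
    high_w = base_w.copy()
    for g in ("psychiatric", "substance_use", "injury", "homelessness"):
        if g in cat_idx:
            high_w[cat_idx[g]] = 3.0
    base_w = base_w / base_w.sum()
    high_w = high_w / high_w.sum()

    # --- visit counts and dates -------------------------------------------
    n_days = (config.end_date - config.start_date).days
    n_visits = np.maximum(rng.poisson(config.visit_rate, size=n), 1)
    total = int(n_visits.sum())
    pat_of_visit = np.repeat(np.arange(n), n_visits)
    day = rng.integers(0, n_days + 1, size=total)
    order = np.lexsort((day, pat_of_visit))
    day = day[order]
    starts = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(n_visits, out=starts[1:])

    # --- category Markov chain (vectorised over patients per step) --------
    stick = 0.45
    max_v = int(n_visits.max())
    cat_seq = np.zeros(total, dtype=np.int64)
    pref = np.where(high_risk[:, None], high_w[None, :], base_w[None, :])
    cum_pref = np.cumsum(pref, axis=1)
    cur = (rng.random(n)[:, None] < cum_pref).argmax(axis=1)
    cat_seq[starts[:-1]] = cur
    for j in range(1, max_v):
        active = n_visits > j
        stay = rng.random(n) < stick
        fresh = (rng.random(n)[:, None] < cum_pref).argmax(axis=1)
        cur = np.where(stay, cur, fresh)
        idx = starts[:-1][active] + j
        cat_seq[idx] = cur[active]

    # --- per-visit code draws ---------------------------------------------
    principal = np.empty(total, dtype=np.int64)
    for k in range(k_cat):
        m = cat_seq == k
        cnt = int(m.sum())
        if cnt and len(codes_by_cat[k]):
            principal[m] = rng.choice(codes_by_cat[k], size=cnt)
    # negative binomial: mean ~5.5, overdispersed so codes per visit land near
    # a median of 7 with a wide IQR, as in statewide discharge data
    n_aux = np.minimum(rng.negative_binomial(2, 2.0 / (2.0 + 5.5), size=total), 24)
    ec_lam = np.where(cat_seq == injury_cat, 1.2, 0.25)
    n_ec = np.minimum(rng.poisson(ec_lam), 5)
    n_proc = np.minimum(rng.poisson(1.2, size=total), 5)

    aux_flat = _draw_aux(rng, cat_seq, n_aux, codes_by_cat, cum_pref, pat_of_visit)
    ec_pool = np.concatenate(
        [codes_by_cat[injury_cat]] if injury_cat >= 0 else [np.arange(len(dx_codes))]
    )
    ec_flat = rng.choice(ec_pool, size=int(n_ec.sum())) if n_ec.sum() else np.empty(0, int)
    proc_flat = rng.integers(0, config.n_proc_codes, size=int(n_proc.sum()))

    # --- pre-index outcome insertions (recurrence substrate) ---------------
    idx_day = _index_day(day, starts, config)
    has_index = idx_day >= 0
    prior_outcome = (rng.random(n) < config.prior_outcome_rate) & (n_visits >= 2)
    prior_code = rng.choice(outcome_code_ids, size=n)
    prior_visit_slot = np.zeros(n, dtype=np.int64)
    for p in np.flatnonzero(prior_outcome):
        lo, hi = starts[p], starts[p + 1]
        pre = np.flatnonzero(day[lo:hi] <= (idx_day[p] if has_index[p] else day[hi - 1]))
        if len(pre) == 0:
            prior_outcome[p] = False
        else:
            prior_visit_slot[p] = lo + rng.integers(0, len(pre))

    # --- outcome hazard ----------------------------------------------------
    exposures = np.zeros(n)
    riskmask = is_risk_code[principal]
    for p in range(n):
        lo, hi = starts[p], starts[p + 1]
        lim = idx_day[p] if has_index[p] else -1
        pre = day[lo:hi] <= lim
        exposures[p] = riskmask[lo:hi][pre].sum()
    aux_expo = _aux_exposures(aux_flat, n_aux, day, idx_day, starts, is_risk_code, n)
    exposures += aux_expo

    age_eff = np.where((age >= 1) & (age <= 3), 0.4, 0.0)
    sex_eff = np.where(sex == 0, 0.2, 0.0)
    lin = (
        config.risk_effect * exposures
        + config.strata_effects * (age_eff + sex_eff)
        + 1.0 * prior_outcome.astype(float)
    )
    lin = np.where(has_index, lin, -np.inf)
    n_eligible = int(has_index.sum())
    if n_eligible == 0:
        intercept = 0.0
        event = np.zeros(n, dtype=bool)
    else:
        target = config.outcome_prevalence_target
        # An outcome visit that still falls inside the index year becomes the
        # patient's new last-visit-of-the-year, i.e. it is absorbed into the
        # index rather than observed as a post-index event. Calibrate the
        # intercept against the probability of an OBSERVED (post-index-year)
        # event: bucket b covers day offsets [30b+1, 30b+30], of which the
        # fraction beyond the remaining days of the index year counts.
        start_ord_cal = config.start_date.toordinal()
        year_end = _dt.date(config.index_year, 12, 31).toordinal() - start_ord_cal
        dte = np.maximum(year_end - idx_day[has_index], 0)  # days to year end
        b_idx = np.arange(_N_HAZARD_BUCKETS)
        obs_frac = np.clip((30.0 * b_idx[None, :] + 30.0 - dte[:, None]) / 30.0, 0, 1)

        def achieved(c: float) -> float:
            q = expit(c + lin[has_index])
            surv = (1.0 - q[:, None]) ** b_idx[None, :]
            p_obs = (q[:, None] * surv * obs_frac).sum(axis=1)
            return float(np.mean(p_obs)) - target

        lo_c, hi_c = -80.0, 5.0
        if achieved(lo_c) > 0 or achieved(hi_c) < 0:
            warnings.warn(
                "outcome prevalence target unreachable; achieved "
                f"{achieved(np.clip(0.0, lo_c, hi_c)) + target:.4f} at intercept 0",
                stacklevel=2,
            )
            intercept = lo_c if achieved(lo_c) > 0 else hi_c
        else:
            intercept = brentq(achieved, lo_c, hi_c)
        q = expit(intercept + lin)
        # first-success bucket among the 12 post-index intervals
        u = rng.random((n, _N_HAZARD_BUCKETS))
        hits = u < q[:, None]
        event = hits.any(axis=1) & has_index
    bucket = hits.argmax(axis=1) if n_eligible else np.zeros(n, dtype=np.int64)
    within = rng.integers(1, 31, size=n)
    event_day = idx_day + bucket * 30 + np.minimum(within, 365 - bucket * 30)

    # --- assemble rows ------------------------------------------------------
    ext_digit = rng.integers(0, 10, size=total + int(n_aux.sum()))
    has_ext = rng.random(total + int(n_aux.sum())) < 0.4
    pids = np.asarray([f"P{i:07d}" for i in range(n)], dtype=object)
    facility = rng.integers(0, 40, size=total + n)

    def fmt(code_id: int, slot: int) -> str:
        c = dx_arr[code_id]
        return f"{c}.{ext_digit[slot]}" if has_ext[slot] else c

    rows: list[tuple] = []
    aux_off = 0
    ec_off = 0
    proc_off = 0
    start_ord = config.start_date.toordinal()
    for v in range(total):
        p = pat_of_visit[v]
        a = n_aux[v]
        aux_ids = list(aux_flat[aux_off : aux_off + a])
        if prior_outcome[p] and prior_visit_slot[p] == v:
            if a < 24:
                aux_ids.append(int(prior_code[p]))
                a += 1
            else:
                aux_ids[-1] = int(prior_code[p])
        aux_s = ";".join(
            fmt(cid, total + aux_off + j) if j < n_aux[v] else dx_arr[cid]
            for j, cid in enumerate(aux_ids)
        )
        ec_s = ";".join(dx_arr[c] for c in ec_flat[ec_off : ec_off + n_ec[v]])
        pr_s = ";".join(proc_codes[c] for c in proc_flat[proc_off : proc_off + n_proc[v]])
        rows.append(
            (
                pids[p],
                _dt.date.fromordinal(start_ord + int(day[v])).isoformat(),
                fmt(principal[v], v),
                aux_s,
                ec_s,
                pr_s,
                f"FAC{facility[v]:02d}",
                AGE_DECADES[age[p]],
                SEXES[sex[p]],
                RACES[race[p]],
                PAYORS[payor[p]],
            )
        )
        aux_off += n_aux[v]
        ec_off += n_ec[v]
        proc_off += n_proc[v]

    # post-index outcome visits
    out_code = rng.choice(outcome_code_ids, size=n)
    for p in np.flatnonzero(event):
        d = int(event_day[p])
        rows.append(
            (
                pids[p],
                _dt.date.fromordinal(start_ord + d).isoformat(),
                str(dx_arr[out_code[p]]),
                str(dx_arr[rng.choice(codes_by_cat[injury_cat])]) if injury_cat >= 0 else "",
                "",
                "",
                f"FAC{facility[total + p]:02d}",
                AGE_DECADES[age[p]],
                SEXES[sex[p]],
                RACES[race[p]],
                PAYORS[payor[p]],
            )
        )

    df = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    df = df.sort_values(["patient_id", "visit_date"], kind="stable").reset_index(drop=True)
    return df


def _draw_aux(rng, cat_seq, n_aux, codes_by_cat, cum_pref, pat_of_visit):
    """Auxiliary diagnosis ids: 60% within the visit category, else per patient preference."""
    total_aux = int(n_aux.sum())
    if total_aux == 0:
        return np.empty(0, dtype=np.int64)
    vis = np.repeat(np.arange(len(cat_seq)), n_aux)
    same = rng.random(total_aux) < 0.6
    cat = np.where(
        same,
        cat_seq[vis],
        (rng.random(total_aux)[:, None] < cum_pref[pat_of_visit[vis]]).argmax(axis=1),
    )
    out = np.empty(total_aux, dtype=np.int64)
    for k in range(len(codes_by_cat)):
        m = cat == k
        cnt = int(m.sum())
        if cnt:
            pool = codes_by_cat[k]
            if len(pool) == 0:
                pool = codes_by_cat[(k + 1) % len(codes_by_cat)]
            out[m] = rng.choice(pool, size=cnt)
    return out


def _aux_exposures(aux_flat, n_aux, day, idx_day, starts, is_risk_code, n):
    """Count pre-index risk-code occurrences among auxiliary diagnoses."""
    if len(aux_flat) == 0:
        return np.zeros(n)
    vis = np.repeat(np.arange(len(n_aux)), n_aux)
    pat = np.searchsorted(starts[1:], vis, side="right")
    pre = day[vis] <= idx_day[pat]
    risky = is_risk_code[aux_flat] & pre & (idx_day[pat] >= 0)
    return np.bincount(pat[risky], minlength=n).astype(float)


def _index_day(day, starts, config: SimConfig):
    """Day offset of each patient's last visit in the index year, or -1."""
    start_ord = config.start_date.toordinal()
    y_lo = _dt.date(config.index_year, 1, 1).toordinal() - start_ord
    y_hi = _dt.date(config.index_year, 12, 31).toordinal() - start_ord
    n = len(starts) - 1
    out = np.full(n, -1, dtype=np.int64)
    for p in range(n):
        seg = day[starts[p] : starts[p + 1]]
        in_year = seg[(seg >= y_lo) & (seg <= y_hi)]
        if len(in_year):
            out[p] = in_year.max()
    return out


@dataclass
class CohortSummary:
    n_patients: int
    n_visits: int
    visits_median: float
    visits_iqr: tuple[float, float]
    codes_per_visit_median: float
    codes_per_visit_iqr: tuple[float, float]
    outcome_prevalence: float | None
    demographics: dict[str, dict[str, float]] = field(default_factory=dict)


def summarize_cohort(
    visits: pd.DataFrame, outcome_codes: frozenset[str] | None = None
) -> CohortSummary:
    """Deterministic cohort-characteristics summary of a visit table."""
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise KeyError(f"visit table missing required columns: {missing}")
    if len(visits) == 0:
        raise ValueError("cannot summarize an empty visit table")

    per_pat = visits.groupby("patient_id", sort=True).size()

    def count_codes(row) -> int:
        k = 1
        for col in ("aux_dx", "ecause", "procedures"):
            v = row[col]
            if isinstance(v, str) and v:
                k += v.count(";") + 1
        return k

    cpv = visits.apply(count_codes, axis=1)
    prevalence = None
    if outcome_codes is not None:
        base = visits["principal_dx"].str.split(".").str[0]
        has = base.isin(outcome_codes)
        aux = visits["aux_dx"].fillna("")
        for oc in outcome_codes:
            has = has | aux.str.contains(rf"(?:^|;){oc}(?:\.|;|$)", regex=True)
        pos_patients = visits.loc[has, "patient_id"].unique()
        prevalence = len(pos_patients) / per_pat.size

    demo = {}
    firsts = visits.groupby("patient_id", sort=True).first()
    for col in ("age_decade", "sex", "race", "payor"):
        demo[col] = (firsts[col].value_counts(normalize=True)).to_dict()

    q1v, q3v = per_pat.quantile([0.25, 0.75])
    q1c, q3c = cpv.quantile([0.25, 0.75])
    return CohortSummary(
        n_patients=int(per_pat.size),
        n_visits=int(len(visits)),
        visits_median=float(per_pat.median()),
        visits_iqr=(float(q1v), float(q3v)),
        codes_per_visit_median=float(cpv.median()),
        codes_per_visit_iqr=(float(q1c), float(q3c)),
        outcome_prevalence=prevalence,
        demographics=demo,
    )
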