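"""Cohort construction: labeled trajectories and fixed-length token sequences.

Rules implemented here:

* index visit = the patient's chronologically last visit in the index year
  (observation of a full subsequent year of data is thereby guaranteed);
* diagnosis codes truncated to their first three characters (after
  punctuation stripping and uppercasing) to group related diagnoses;
* binary label = any outcome code dated within (index, index + 365 days];
  outcome codes at or before the index set ``prior_outcome`` instead, and a
  first-event filter removes such trajectories for the first-event analysis;
* days-before-index grouped into seven temporal buckets
  (0, 1-29, 30-89, 90-179, 180-359, 360-719, 720+);
* sequences fixed to 512 positions: [CLS], demographic tokens, then visit
  features oldest to newest, each carrying (code, code-type, time-bucket)
  ids; over-long inputs drop their oldest visit features, short inputs are
  padded with a suffix of PAD tokens ignored by the encoder;
* patient-level 95:5 (pretraining) and 9:1 (fine-tuning) splits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PAD_ID",
    "MASK_ID",
    "CLS_ID",
    "UNK_ID",
    "N_SPECIAL",
    "TYPE_SPECIAL",
    "TYPE_DEMO",
    "TYPE_PRINCIPAL",
    "TYPE_AUX",
    "TYPE_ECAUSE",
    "TYPE_PROC",
    "TIME_PAD_BUCKET",
    "Visit",
    "Trajectory",
    "CodeVocabulary",
    "TokenizedTrajectory",
    "CohortSplit",
    "truncate_dx_code",
    "short_code_warnings",
    "reset_short_code_warnings",
    "bucket_day_offset",
    "select_index_visit",
    "build_trajectories",
    "filter_first_event",
    "split_patients",
    "build_vocabulary",
    "tokenize",
    "stack_tokenized",
]

# special token ids (reserved, dense from 0)
PAD_ID, MASK_ID, CLS_ID, UNK_ID = 0, 1, 2, 3
N_SPECIAL = 4
SPECIAL_TOKENS = ["[PAD]", "[MASK]", "[CLS]", "[UNK]"]

# code-type ids: every embedded feature carries one
TYPE_SPECIAL, TYPE_DEMO, TYPE_PRINCIPAL, TYPE_AUX, TYPE_ECAUSE, TYPE_PROC = range(6)

#: temporal bucket assigned to padding positions (real buckets are 0..6)
TIME_PAD_BUCKET = 7

_BUCKET_EDGES = (1, 30, 90, 180, 360, 720)  # lower edges of buckets 1..6
_PUNCT_RE = re.compile(r"[^A-Za-z0-9]")

_short_code_count = 0


def short_code_warnings() -> int:
    """Number of codes seen so far that were too short to truncate."""
    return _short_code_count


def reset_short_code_warnings() -> None:
    global _short_code_count
    _short_code_count = 0


def truncate_dx_code(code: str) -> str:
    """First three characters of a diagnosis code, grouping related diagnoses.

    Punctuation is stripped and the code uppercased first, so ``"T74.11XA"``
    and ``"t74-11"`` both map to ``"T74"``. Codes shorter than three
    characters after stripping are returned unchanged and counted.
    """
    global _short_code_count
    if not code:
        raise ValueError("empty diagnosis code")
    stripped = _PUNCT_RE.sub("", code).upper()
    if len(stripped) < 3:
        _short_code_count += 1
        return stripped
    return stripped[:3]


def bucket_day_offset(days_before_index: int) -> int:
    """Map a non-negative days-before-index offset to one of seven buckets.

    Boundaries: 0 | 1-29 | 30-89 | 90-179 | 180-359 | 360-719 | 720+.
    """
    d = int(days_before_index)
    if d < 0:
        raise ValueError("visits after the index cannot be model inputs")
    b = 0
    for edge in _BUCKET_EDGES:
        if d >= edge:
            b += 1
    return b


@dataclass
class Visit:
    date: pd.Timestamp
    principal_dx: str
    aux_dx: list[str]
    ecause: list[str]
    procedures: list[str]


@dataclass
class Trajectory:
    """A patient's ordered input visits anchored at the index visit."""

    patient_id: str
    visits: list[Visit]  # ascending by date; last visit is the index visit
    index_date: pd.Timestamp
    label: int
    prior_outcome: bool
    lag_days: int | None  # days from index to first post-index outcome
    demographics: dict[str, str] = field(default_factory=dict)


def _split_codes(value) -> list[str]:
    if isinstance(value, str) and value:
        return value.split(";")
    if isinstance(value, list):
        return value
    return []


def select_index_visit(visit_dates: pd.Series, index_year: int):
    """Positional index of the last visit in ``index_year``, or ``None``.

    Ties on the same date resolve to the later row in stable input order.
    """
    in_year = visit_dates.dt.year == index_year
    if not in_year.any():
        return None
    dates = visit_dates[in_year]
    last_date = dates.max()
    return int(dates[dates == last_date].index[-1])


def build_trajectories(
    visits: pd.DataFrame,
    outcome_codes: frozenset[str] | set[str],
    index_year: int,
    min_visits: int = 3,
    horizon_days: int = 365,
) -> list[Trajectory]:
    """Build one labeled trajectory per retained patient.

    The input span is every visit dated at or before the index visit. The
    label is positive iff any outcome code falls strictly after the index
    date and within ``horizon_days`` of it; outcome codes at or before the
    index only set ``prior_outcome``. Patients with fewer than
    ``min_visits`` input visits, or with no visit in ``index_year``, are
    excluded.
    """
    if len(visits) == 0:
        raise ValueError("empty visit table")
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    required = {"patient_id", "visit_date", "principal_dx"}
    missing = required - set(visits.columns)
    if missing:
        raise KeyError(f"visit table missing required columns: {sorted(missing)}")

    df = visits.copy()
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    df = df.sort_values(["patient_id", "visit_date"], kind="stable").reset_index(drop=True)
    outcome_codes = frozenset(outcome_codes)

    pid = df["patient_id"].to_numpy(dtype=object)
    ts = df["visit_date"].tolist()
    days = df["visit_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    years = df["visit_date"].dt.year.to_numpy()

    memo: dict[str, str] = {}

    def trunc(c: str) -> str:
        r = memo.get(c)
        if r is None:
            r = memo[c] = truncate_dx_code(c)
        return r

    def col(name) -> list:
        if name in df.columns:
            return df[name].fillna("").tolist()
        return [""] * len(df)

    principal = [trunc(c) for c in df["principal_dx"].tolist()]
    aux = [[trunc(x) for x in _split_codes(s)] for s in col("aux_dx")]
    ecause = [[trunc(x) for x in _split_codes(s)] for s in col("ecause")]
    procs = [_split_codes(s) for s in col("procedures")]
    has_outcome = np.asarray(
        [
            principal[i] in outcome_codes
            or any(c in outcome_codes for c in aux[i])
            or any(c in outcome_codes for c in ecause[i])
            for i in range(len(df))
        ]
    )
    demo_cols = {
        k: df[k].tolist() for k in ("age_decade", "sex", "race", "payor") if k in df.columns
    }

    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    ends = np.r_[starts[1:], len(df)]

    out: list[Trajectory] = []
    for lo, hi in zip(starts, ends):
        in_year = np.flatnonzero(years[lo:hi] == index_year)
        if len(in_year) == 0:
            continue
        # rows are date-sorted, so the last in-year row is the latest in-year
        # visit; same-date ties resolve to the later row by stable order
        idx_pos = lo + int(in_year[-1])
        index_day = days[idx_pos]
        if idx_pos - lo + 1 < min_visits:
            continue
        prior = False
        lag = None
        for i in range(lo, hi):
            if not has_outcome[i]:
                continue
            delta = int(days[i] - index_day)
            if delta <= 0:
                prior = True
            elif delta <= horizon_days and lag is None:
                lag = delta
        label = int(lag is not None)
        vis = [
            Visit(
                date=ts[i],
                principal_dx=principal[i],
                aux_dx=aux[i],
                ecause=ecause[i],
                procedures=procs[i],
            )
            for i in range(lo, idx_pos + 1)
        ]
        out.append(
            Trajectory(
                patient_id=str(pid[lo]),
                visits=vis,
                index_date=ts[idx_pos],
                label=label,
                prior_outcome=prior,
                lag_days=lag,
                demographics={k: str(v[idx_pos]) for k, v in demo_cols.items()},
            )
        )
    return out


def filter_first_event(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Drop trajectories with an outcome diagnosis at or before the index."""
    return [t for t in trajectories if not t.prior_outcome]


@dataclass
class CohortSplit:
    kind: str
    seed: int
    splits: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = [pid for s in self.splits.values() for pid in s]
        if len(ids) != len(set(ids)):
            raise ValueError("patient appears in more than one split")


def split_patients(patient_ids, kind: str, seed: int) -> CohortSplit:
    """Seed-deterministic patient-level splits.

    ``kind="pretrain"`` gives a 95:5 dev/test split; ``kind="finetune"``
    gives a 9:1 dev/test split with the dev portion sub-split 9:1 into
    train/val.
    """
    ids = sorted(set(map(str, patient_ids)))
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    perm = list(np.asarray(ids, dtype=object)[rng.permutation(len(ids))])
    if kind == "pretrain":
        n_dev = round(0.95 * len(perm))
        splits = {"dev": frozenset(perm[:n_dev]), "test": frozenset(perm[n_dev:])}
    elif kind == "finetune":
        n_dev = round(0.9 * len(perm))
        dev, test = perm[:n_dev], perm[n_dev:]
        n_train = round(0.9 * len(dev))
        splits = {
            "train": frozenset(dev[:n_train]),
            "val": frozenset(dev[n_train:]),
            "test": frozenset(test),
        }
    else:
        raise ValueError(f"unknown split kind: {kind!r}")
    return CohortSplit(kind=kind, seed=seed, splits=splits)


class CodeVocabulary:
    """Bidirectional token/id map with reserved specials and counts.

    Ids are dense: 0-3 are [PAD]/[MASK]/[CLS]/[UNK]; the rest are assigned
    to tokens in decreasing count order (ties alphabetical). Tokens below
    ``min_count`` encode to UNK.
    """

    def __init__(self, counts: dict[str, int], min_count: int = 1) -> None:
        self.counts = dict(counts)
        kept = sorted(
            (t for t, c in counts.items() if c >= min_count),
            key=lambda t: (-counts[t], t),
        )
        self.id_to_token = list(SPECIAL_TOKENS) + kept
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def decode(self, idx: int) -> str:
        return self.id_to_token[idx]


def demographic_tokens(demographics: dict[str, str]) -> list[str]:
    """Stable-order demographic tokens (taken from the index visit)."""
    order = ("age_decade", "sex", "race", "payor")
    return [f"{k.upper()}={demographics[k]}" for k in order if k in demographics]


def build_vocabulary(trajectories: list[Trajectory], min_count: int = 1) -> CodeVocabulary:
    """Vocabulary over demographic, diagnosis, external-cause and procedure tokens."""
    if not trajectories:
        raise ValueError("cannot build a vocabulary from an empty cohort")
    counts: dict[str, int] = {}

    def bump(tok: str) -> None:
        counts[tok] = counts.get(tok, 0) + 1

    for t in trajectories:
        for tok in demographic_tokens(t.demographics):
            bump(tok)
        for v in t.visits:
            bump(v.principal_dx)
            for c in v.aux_dx:
                bump(c)
            for c in v.ecause:
                bump(c)
            for c in v.procedures:
                bump(c)
    return CodeVocabulary(counts, min_count=min_count)


@dataclass
class TokenizedTrajectory:
    """Fixed-length parallel (code, type, time-bucket) id sequences.

    ``visit_index`` maps each position to the ordinal of the source visit
    (-1 for CLS/demographics/padding); ``day_offsets`` records the
    days-before-index of each visit feature (-1 elsewhere).
    """

    patient_id: str
    code_ids: np.ndarray
    type_ids: np.ndarray
    time_bucket_ids: np.ndarray
    attention_mask: np.ndarray
    visit_index: np.ndarray
    day_offsets: np.ndarray
    label: int

    def __post_init__(self) -> None:
        n = len(self.code_ids)
        for arr in (self.type_ids, self.time_bucket_ids, self.attention_mask):
            if len(arr) != n:
                raise ValueError("parallel sequences must have equal length")


def tokenize(
    trajectory: Trajectory,
    vocab: CodeVocabulary,
    max_len: int = 512,
    index_date: pd.Timestamp | None = None,
) -> TokenizedTrajectory:
    """Convert a trajectory into fixed-length id sequences.

    Layout: position 0 is [CLS] (time bucket 0), demographic tokens follow
    (time bucket 0), then visit features oldest to newest. If the sequence
    exceeds ``max_len`` the oldest visit features are dropped first — never
    [CLS] or demographics; the newest visit is kept intact whenever it fits.
    Padding is a contiguous suffix. ``index_date`` overrides the temporal
    anchor (used by the next-visit pretraining task).
    """
    anchor = trajectory.index_date if index_date is None else index_date
    demos = demographic_tokens(trajectory.demographics)
    n_fixed = 1 + len(demos)
    if max_len < n_fixed + 1:
        raise ValueError(f"max_len={max_len} cannot hold CLS + demographics + 1 feature")

    feats: list[tuple[int, int, int, int, int]] = []  # code, type, bucket, visit, day
    for vi, v in enumerate(trajectory.visits):
        days = (anchor - v.date).days
        if days < 0:
            continue  # visits after the anchor are never inputs
        bucket = bucket_day_offset(days)
        feats.append((vocab.encode(v.principal_dx), TYPE_PRINCIPAL, bucket, vi, days))
        for c in v.aux_dx:
            feats.append((vocab.encode(c), TYPE_AUX, bucket, vi, days))
        for c in v.ecause:
            feats.append((vocab.encode(c), TYPE_ECAUSE, bucket, vi, days))
        for c in v.procedures:
            feats.append((vocab.encode(c), TYPE_PROC, bucket, vi, days))

    room = max_len - n_fixed
    if len(feats) > room:
        feats = feats[len(feats) - room :]

    code = np.full(max_len, PAD_ID, dtype=np.int64)
    typ = np.full(max_len, TYPE_SPECIAL, dtype=np.int64)
    tim = np.full(max_len, TIME_PAD_BUCKET, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    vis = np.full(max_len, -1, dtype=np.int64)
    dayo = np.full(max_len, -1, dtype=np.int64)

    code[0], typ[0], tim[0], mask[0] = CLS_ID, TYPE_SPECIAL, 0, 1
    for j, tok in enumerate(demos, start=1):
        code[j], typ[j], tim[j], mask[j] = vocab.encode(tok), TYPE_DEMO, 0, 1
    for j, (c, t, b, vi, d) in enumerate(feats, start=n_fixed):
        code[j], typ[j], tim[j], mask[j] = c, t, b, 1
        vis[j], dayo[j] = vi, d

    return TokenizedTrajectory(
        patient_id=trajectory.patient_id,
        code_ids=code,
        type_ids=typ,
        time_bucket_ids=tim,
        attention_mask=mask,
        visit_index=vis,
        day_offsets=dayo,
        label=trajectory.label,
    )


def stack_tokenized(toks: list[TokenizedTrajectory]) -> dict[str, np.ndarray]:
    """Stack tokenized trajectories into batch arrays."""
    return {
        "code_ids": np.stack([t.code_ids for t in toks]),
        "type_ids": np.stack([t.type_ids for t in toks]),
        "time_bucket_ids": np.stack([t.time_bucket_ids for t in toks]),
        "attention_mask": np.stack([t.attention_mask for t in toks]),
        "labels": np.asarray([t.label for t in toks], dtype=np.int64),
        "patient_ids": np.asarray([t.patient_id for t in toks], dtype=object),
    }
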