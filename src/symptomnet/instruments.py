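"""Rating-instrument schemas and validated cohort I/O.

Three clinician-rated instruments make up the 43-node item set used
throughout the package:

* **PANSS** — Positive and Negative Syndrome Scale, 30 items scored 1-7
  (7 positive ``P1``-``P7``, 7 negative ``N1``-``N7``, 16 general
  psychopathology ``G1``-``G16``).
* **CDSS** — Calgary Depression Scale for Schizophrenia, 9 items scored 0-3.
* **PSP** — Personal and Social Performance scale, 4 domain subscores
  scored 0-6 where higher means worse functioning.  The global PSP total
  (0-100, higher = better) is carried as optional per-participant metadata
  and is never a network node.

The default community partition groups nodes into five blocks
(PANSS-positive, PANSS-negative, PANSS-general, CDSS, PSP), which is the
partition the bridge statistics use unless the caller supplies another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEMOGRAPHIC_COLUMNS = ("participant_id", "age", "sex", "psp_total")


@dataclass(frozen=True)
class ItemDef:
    """One rating-scale item: identity, instrument, subscale and score range."""

    id: str
    label: str
    instrument: str  # PANSS | CDSS | PSP
    subscale: str  # positive | negative | general | depression | functioning
    min_score: int
    max_score: int
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValueError(f"item {self.id}: empty score range")

    @property
    def n_categories(self) -> int:
        return self.max_score - self.min_score + 1


@dataclass(frozen=True)
class ItemSchema:
    """Ordered item list plus the node -> community mapping."""

    items: tuple[ItemDef, ...]
    communities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in schema")
        missing = [i for i in ids if i not in self.communities]
        if missing:
            raise ValueError(f"items without a community: {missing}")

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def community_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for it in self.items:
            c = self.communities[it.id]
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def community_labels(self) -> np.ndarray:
        """Community label per item, in schema order."""
        return np.asarray([self.communities[i] for i in self.ids])

    def to_json(self, path) -> None:
        payload = {
            "items": [vars(it) for it in self.items],
            "communities": self.communities,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemSchema":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        items = tuple(ItemDef(**d) for d in payload["items"])
        return cls(items=items, communities=dict(payload["communities"]))


@dataclass
class CohortTable:
    """Participants x items integer score matrix aligned to an ItemSchema."""

    schema: ItemSchema
    scores: np.ndarray  # (n, p) int
    participant_ids: list[str]
    demographics: pd.DataFrame | None = None  # columns subset of {age, sex}
    psp_total: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != self.schema.n_items:
            raise ValueError(
                f"scores must be (n, {self.schema.n_items}), got {self.scores.shape}"
            )
        if len(self.participant_ids) != self.scores.shape[0]:
            raise ValueError("participant_ids length mismatch")
        if self.psp_total is not None:
            self.psp_total = np.asarray(self.psp_total)
            if np.any((self.psp_total < 0) | (self.psp_total > 100)):
                raise ValueError("psp_total outside [0, 100]")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.schema.ids)
        df.insert(0, "participant_id", self.participant_ids)
        if self.demographics is not None:
            for col in self.demographics.columns:
                df[col] = np.asarray(self.demographics[col])
        if self.psp_total is not None:
            df["psp_total"] = self.psp_total
        return df

    def validate(self) -> None:
        """Raise if any score falls outside its item's range."""
        bad = _range_violations(self.scores, self.schema)
        if bad:
            r, c = bad[0]
            item = self.schema.items[c]
            raise ValueError(
                f"score out of range at row {r}, item {item.id}: "
                f"{self.scores[r, c]} not in [{item.min_score}, {item.max_score}]"
                + (f" ({len(bad)} violations total)" if len(bad) > 1 else "")
            )


# ---------------------------------------------------------------------------
# Default 43-item schema

_PANSS_POSITIVE = [
    ("P1", "Delusions"),
    ("P2", "Conceptual Disorganization"),
    ("P3", "Hallucinatory Behavior"),
    ("P4", "Excitement"),
    ("P5", "Grandiosity"),
    ("P6", "Suspiciousness/Persecution"),
    ("P7", "Hostility"),
]
_PANSS_NEGATIVE = [
    ("N1", "Blunted Affect"),
    ("N2", "Emotional Withdrawal"),
    ("N3", "Poor Rapport"),
    ("N4", "Passive/Apathetic Social Withdrawal"),
    ("N5", "Difficulty in Abstract Thinking"),
    ("N6", "Lack of Spontaneity and Flow of Conversation"),
    ("N7", "Stereotyped Thinking"),
]
_PANSS_GENERAL = [
    ("G1", "Somatic Concern"),
    ("G2", "Anxiety"),
    ("G3", "Guilty Feelings"),
    ("G4", "Tension"),
    ("G5", "Mannerisms and Posturing"),
    ("G6", "Depression"),
    ("G7", "Motor Retardation"),
    ("G8", "Uncooperativeness"),
    ("G9", "Unusual Thought Content"),
    ("G10", "Disorientation"),
    ("G11", "Poor Attention"),
    ("G12", "Lack of Judgment and Insight"),
    ("G13", "Disturbance of Volition"),
    ("G14", "Poor Impulse Control"),
    ("G15", "Preoccupation"),
    ("G16", "Active Social Avoidance"),
]
_CDSS = [
    ("CDSS1", "Depressed Mood"),
    ("CDSS2", "Hopelessness"),
    ("CDSS3", "Self-Depreciation"),
    ("CDSS4", "Guilty Ideas of Reference"),
    ("CDSS5", "Pathological Guilt"),
    ("CDSS6", "Morning Depression"),
    ("CDSS7", "Early Wakening"),
    ("CDSS8", "Suicide"),
    ("CDSS9", "Observed Depression"),
]
_PSP = [
    ("PSP-A", "Socially Useful Activities"),
    ("PSP-B", "Personal and Social Relationships"),
    ("PSP-C", "Self-Care"),
    ("PSP-D", "Disturbing and Aggressive Behavior"),
]

COMMUNITY_POSITIVE = "PANSS-positive"
COMMUNITY_NEGATIVE = "PANSS-negative"
COMMUNITY_GENERAL = "PANSS-general"
COMMUNITY_CDSS = "CDSS"
COMMUNITY_PSP = "PSP"


def default_schema() -> ItemSchema:
    """The canonical 43-item schema in subscale-then-number order.

    Item order is fixed (P1-P7, N1-N7, G1-G16, CDSS1-CDSS9, PSP-A..D) so
    every matrix produced by the package is comparable across runs.  The
    default community partition has five blocks of sizes (7, 7, 16, 9, 4).
    """
    items: list[ItemDef] = []
    communities: dict[str, str] = {}
    blocks = [
        (_PANSS_POSITIVE, "PANSS", "positive", 1, 7, COMMUNITY_POSITIVE),
        (_PANSS_NEGATIVE, "PANSS", "negative", 1, 7, COMMUNITY_NEGATIVE),
        (_PANSS_GENERAL, "PANSS", "general", 1, 7, COMMUNITY_GENERAL),
        (_CDSS, "CDSS", "depression", 0, 3, COMMUNITY_CDSS),
        (_PSP, "PSP", "functioning", 0, 6, COMMUNITY_PSP),
    ]
    for defs, instrument, subscale, lo, hi, community in blocks:
        for item_id, label in defs:
            items.append(
                ItemDef(
                    id=item_id,
                    label=label,
                    instrument=instrument,
                    subscale=subscale,
                    min_score=lo,
                    max_score=hi,
                    higher_is_worse=True,
                )
            )
            communities[item_id] = community
    return ItemSchema(items=tuple(items), communities=communities)


# ---------------------------------------------------------------------------
# Cohort CSV I/O


def _range_violations(scores: np.ndarray, schema: ItemSchema) -> list[tuple[int, int]]:
    lo = np.array([it.min_score for it in schema.items])
    hi = np.array([it.max_score for it in schema.items])
    bad = (scores < lo) | (scores > hi)
    rows, cols = np.nonzero(bad)
    return list(zip(rows.tolist(), cols.tolist()))


def read_cohort(path, schema: ItemSchema, strict: bool = True) -> CohortTable:
    """Read a cohort CSV, reorder columns to schema order and validate ranges.

    Parameters
    ----------
    path : str or path-like
        CSV with a header of item ids (any order) and optional
        ``participant_id``, ``age``, ``sex``, ``psp_total`` columns.
    schema : ItemSchema
        Column set and valid ranges.
    strict : bool
        If True, any missing or out-of-range cell aborts with row/column
        diagnostics.  If False, offending rows are dropped and the drop
        count is logged.
    """
    df = pd.read_csv(path)
    missing_cols = [i for i in schema.ids if i not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing required item columns: {missing_cols}")

    raw = df[schema.ids]
    # locate non-numeric cells before casting
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    non_numeric = numeric.isna() & raw.notna()
    if non_numeric.any().any():
        r, c = next(zip(*np.nonzero(non_numeric.to_numpy())))
        if strict:
            raise ValueError(
                f"non-integer cell at row {r}, column {raw.columns[c]}: "
                f"{raw.iat[r, c]!r}"
            )
    frac = numeric.notna() & (numeric != numeric.round())
    if strict and frac.any().any():
        r, c = next(zip(*np.nonzero(frac.to_numpy())))
        raise ValueError(
            f"non-integer cell at row {r}, column {raw.columns[c]}: {raw.iat[r, c]!r}"
        )

    keep = numeric.notna().all(axis=1) & ~frac.any(axis=1)
    lo = np.array([it.min_score for it in schema.items])
    hi = np.array([it.max_score for it in schema.items])
    vals = numeric.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        in_range = np.where(np.isnan(vals), False, (vals >= lo) & (vals <= hi))
    if strict:
        if not keep.all():
            r = int(np.nonzero(~keep.to_numpy())[0][0])
            c = int(np.nonzero(numeric.iloc[r].isna().to_numpy())[0][0])
            raise ValueError(f"missing value at row {r}, column {schema.ids[c]}")
        bad = ~in_range
        if bad.any():
            r, c = map(int, next(zip(*np.nonzero(bad))))
            item = schema.items[c]
            raise ValueError(
                f"score out of range at row {r}, item {item.id}: "
                f"{vals[r, c]:g} not in [{item.min_score}, {item.max_score}]"
            )
    keep = keep.to_numpy() & in_range.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("read_cohort: dropped %d row(s) failing validation", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    scores = numeric.loc[keep].to_numpy(dtype=np.int64)

    if "participant_id" in df.columns:
        participant_ids = df["participant_id"].astype(str).tolist()
    else:
        participant_ids = [str(i) for i in range(len(df))]
    demo_cols = [c for c in ("age", "sex") if c in df.columns]
    demographics = df[demo_cols].copy() if demo_cols else None
    psp_total = (
        df["psp_total"].to_numpy(dtype=np.int64) if "psp_total" in df.columns else None
    )
    table = CohortTable(
        schema=schema,
        scores=scores,
        participant_ids=participant_ids,
        demographics=demographics,
        psp_total=psp_total,
    )
    table.n_dropped = n_dropped  # type: ignore[attr-defined]
    return table


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort to CSV such that ``read_cohort`` round-trips exactly.

    Layout: ``participant_id``, item columns in schema order, then any
    demographic columns, then ``psp_total``.
    """
    table.validate()
    table.to_frame().to_csv(path, index=False)
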