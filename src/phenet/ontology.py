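"""Ontology subsumption: collapse term-level observations into superclass counts.

Deep-phenotyped cohorts record each subject's cumulative signs and symptoms as
terms from a controlled vocabulary.  Subsumption replaces every term by its
superclass (an ancestor in the ontology), reducing hundreds of terms to a small
fixed feature set.  This module loads a flat term→superclass table, deduplicates
(subject, term) pairs — a sign is either present or absent in a cumulative
record — and produces a subjects × superclasses count matrix.

The packaged default map (``data/superclass_map.synthetic.csv``) is a synthetic,
best-effort vocabulary of 244 neurological sign/symptom terms under the 16
canonical superclasses; real analyses should supply their own mapping table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: The 16 canonical symptom superclasses, in canonical (alphabetical) order.
CANONICAL_SUPERCLASSES: tuple[str, ...] = (
    "behavior",
    "cognitive",
    "cranial nerve",
    "eye movement",
    "fatigue",
    "gait",
    "hyperreflexia",
    "hypertonia",
    "incoordination",
    "pain",
    "sensory",
    "speech",
    "sphincter",
    "tremor",
    "vision",
    "weakness",
)

_DEFAULT_MAP_RESOURCE = "superclass_map.synthetic.csv"


class AmbiguousMappingError(ValueError):
    """A term is mapped to more than one superclass."""


class UnmappedTermError(KeyError):
    """An observed term has no entry in the superclass map."""


@dataclass(frozen=True)
class TermObservation:
    """One coded sign/symptom for one subject."""

    subject_id: str
    term_id: str
    term_label: str = ""

    def __post_init__(self) -> None:
        if not str(self.subject_id):
            raise ValueError("subject_id must be non-empty")
        if not str(self.term_id):
            raise ValueError("term_id must be non-empty")


@dataclass(frozen=True)
class SuperclassMap:
    """Flat term→superclass table with a closed, ordered superclass set."""

    entries: Mapping[str, str]
    superclasses: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        scs = tuple(self.superclasses) or tuple(sorted(set(self.entries.values())))
        object.__setattr__(self, "superclasses", scs)
        unknown = set(self.entries.values()) - set(scs)
        if unknown:
            raise ValueError(
                f"terms mapped to superclasses outside the declared set: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, term_id: str) -> str:
        return self.entries[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.entries

    def terms_by_superclass(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {sc: [] for sc in self.superclasses}
        for term, sc in self.entries.items():
            out[sc].append(term)
        return out


def _normalize_name(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def load_superclass_map(
    path: str | Path,
    canonical: Sequence[str] | None = None,
) -> SuperclassMap:
    """Load a two-column (term_id, superclass) CSV/TSV into a :class:`SuperclassMap`.

    Superclass names are case-folded and whitespace-normalized.  A term mapped
    to two different superclasses is a hard error; so is a superclass outside
    ``canonical`` when a canonical list is enforced.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (term_id, superclass)")
    term_col, sc_col = df.columns[0], df.columns[1]
    entries: dict[str, str] = {}
    for term, sc in zip(df[term_col], df[sc_col]):
        term = str(term).strip()
        sc = _normalize_name(sc)
        if term in entries and entries[term] != sc:
            raise AmbiguousMappingError(
                f"ambiguous mapping for {term!r}: {entries[term]!r} vs {sc!r}"
            )
        entries[term] = sc
    if canonical is not None:
        canonical = tuple(_normalize_name(c) for c in canonical)
        bad = sorted(set(entries.values()) - set(canonical))
        if bad:
            raise ValueError(f"superclasses outside the canonical set: {bad}")
        return SuperclassMap(entries, canonical)
    return SuperclassMap(entries)


def default_superclass_map() -> SuperclassMap:
    """The packaged synthetic default map: 244 terms → the 16 canonical superclasses."""
    ref = resources.files("phenet.data").joinpath(_DEFAULT_MAP_RESOURCE)
    with resources.as_file(ref) as p:
        return load_superclass_map(p, canonical=CANONICAL_SUPERCLASSES)


def load_observations(path: str | Path) -> pd.DataFrame:
    """Read a subject×observation table (subject_id, term_id[, term_label])."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"subject_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if "term_label" not in df.columns:
        df["term_label"] = ""
    return df[["subject_id", "term_id", "term_label"]]


def _observations_frame(
    observations: pd.DataFrame | Iterable[TermObservation],
) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
        if "term_label" not in df.columns:
            df["term_label"] = ""
    else:
        rows = list(observations)
        df = pd.DataFrame(
            {
                "subject_id": [o.subject_id for o in rows],
                "term_id": [o.term_id for o in rows],
                "term_label": [o.term_label for o in rows],
            }
        )
    if df.empty:
        raise ValueError("observations must be non-empty")
    if (df["subject_id"].astype(str) == "").any() or (df["term_id"].astype(str) == "").any():
        raise ValueError("subject_id and term_id must be non-empty")
    return df


class SubsumptionTransformer(BaseEstimator, TransformerMixin):
    """Collapse term observations into superclass counts (feature reduction).

    A scikit-learn transformer: ``transform`` takes a long-format observation
    table (``subject_id``, ``term_id``) and returns a subjects × superclasses
    integer count :class:`~pandas.DataFrame`.  Duplicate (subject, term) pairs
    are deduplicated first; counts > 1 arise only from distinct terms.

    Parameters
    ----------
    mapping : SuperclassMap or None
        Term→superclass table.  ``None`` uses the packaged synthetic default.
    unmapped_policy : {"error", "skip"}
        What to do with a term absent from the map.  ``"error"`` (default)
        raises naming the term and subject; ``"skip"`` drops and logs it.
    """

    def __init__(self, mapping: SuperclassMap | None = None, unmapped_policy: str = "error"):
        self.mapping = mapping
        self.unmapped_policy = unmapped_policy

    def fit(self, X=None, y=None) -> "SubsumptionTransformer":
        if self.unmapped_policy not in ("error", "skip"):
            raise ValueError(f"unmapped_policy must be 'error' or 'skip', got {self.unmapped_policy!r}")
        self.mapping_ = self.mapping if self.mapping is not None else default_superclass_map()
        return self

    def transform(self, X: pd.DataFrame | Iterable[TermObservation]) -> pd.DataFrame:
        if not hasattr(self, "mapping_"):
            self.fit()
        df = _observations_frame(X)
        pairs = df[["subject_id", "term_id"]].drop_duplicates()
        mapped = pairs["term_id"].map(dict(self.mapping_.entries))
        missing = mapped.isna()
        self.n_skipped_ = 0
        self.skipped_terms_: list[str] = []
        if missing.any():
            offenders = pairs[missing]
            if self.unmapped_policy == "error":
                first = offenders.iloc[0]
                raise UnmappedTermError(
                    f"unmapped term {first['term_id']!r} for subject {first['subject_id']!r} "
                    f"({int(missing.sum())} unmapped pairs total)"
                )
            self.skipped_terms_ = sorted(offenders["term_id"].unique())
            self.n_skipped_ = int(missing.sum())
            for t in self.skipped_terms_:
                logger.warning("skipping unmapped term %r", t)
            pairs = pairs[~missing]
            mapped = mapped[~missing]
        counted = (
            pd.DataFrame({"subject_id": pairs["subject_id"], "superclass": mapped})
            .groupby(["subject_id", "superclass"], sort=False)
            .size()
            .unstack(fill_value=0)
        )
        subjects = pd.unique(df["subject_id"])  # first-appearance order
        counts = counted.reindex(
            index=[s for s in subjects if s in counted.index],
            columns=list(self.mapping_.superclasses),
            fill_value=0,
        ).astype(int)
        counts.index.name = "subject_id"
        return counts


def subsume(
    observations: pd.DataFrame | Iterable[TermObservation],
    mapping: SuperclassMap | None = None,
    unmapped_policy: str = "error",
) -> pd.DataFrame:
    """Functional wrapper over :class:`SubsumptionTransformer`."""
    return SubsumptionTransformer(mapping, unmapped_policy).fit().transform(observations)


def filter_empty_subjects(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop all-zero rows (subjects with no mapped findings); report who was dropped.

    Mirrors the exclusion of subjects with normal neurological examinations.
    Idempotent; raises if every subject would be removed.
    """
    empty = counts.sum(axis=1) == 0
    excluded = list(counts.index[empty])
    if len(excluded) == len(counts):
        raise ValueError("all subjects have empty records; nothing to analyze")
    if excluded:
        logger.info("excluded %d subject(s) with empty records: %s", len(excluded), excluded)
    return counts.loc[~empty], excluded
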