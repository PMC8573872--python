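"""Temporal and logical operators shared by all phenotype definitions.

The 19 operational definitions are composed from a small set of primitives:

* :func:`group_episodes` — merge dated events separated by at most a gap into
  care *episodes*, so that a diagnosis and its treatment follow-up count once;
* :func:`max_count_in_window` — the maximum number of episode onsets inside
  any rolling day-granular window (e.g. "3 or more episodes within 12 months");
* :func:`recurrent_documentation` — "documented at least twice in a 6-month or
  greater span, including a specialist's diagnosis at least once";
* :func:`link_within` — pair events from two streams whose dates fall within a
  linkage window ("diagnosis related to the cultured source");
* :class:`CriterionTree` / :func:`eval_tree` — the AND / OR / AND-OR
  combinator grammar over labeled criteria.  "AND/OR" is inclusive
  disjunction; it is kept as a distinct node kind only so that a definition
  displays with the connective text it was ratified with.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

from .errors import ContractError

DateKey = Callable[[Any], dt.date]


def _date_of(event) -> dt.date:
    return event if isinstance(event, dt.date) else event.date


@dataclass(frozen=True)
class Episode:
    """A maximal run of events whose consecutive dates differ by <= gap_days."""

    start: dt.date
    end: dt.date
    events: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("episode start must not exceed end")


def group_episodes(events: Sequence, gap_days: int) -> list[Episode]:
    """Cluster date-sorted events into episodes by transitive date proximity.

    Consecutive events at most ``gap_days`` apart belong to one episode.
    Duplicate events are collapsed, so re-submitting the same fact never
    changes the partition.  Raises :class:`ContractError` on unsorted input.
    """
    if gap_days <= 0:
        raise ContractError("gap_days must be positive")
    dates = [_date_of(e) for e in events]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ContractError("group_episodes requires date-sorted input")

    deduped: list = []
    seen = set()
    for ev in events:
        key = ev if _hashable(ev) else id(ev)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(ev)

    episodes: list[Episode] = []
    current: list = []
    for ev in deduped:
        if current and (_date_of(ev) - _date_of(current[-1])).days > gap_days:
            episodes.append(_make_episode(current))
            current = []
        current.append(ev)
    if current:
        episodes.append(_make_episode(current))
    return episodes


def _hashable(obj) -> bool:
    try:
        hash(obj)
        return True
    except TypeError:
        return False


def _make_episode(events: list) -> Episode:
    return Episode(start=_date_of(events[0]), end=_date_of(events[-1]), events=tuple(events))


def max_count_in_window(episodes: Sequence[Episode], window_days: int) -> int:
    """Maximum number of episode starts in any closed window of ``window_days`` days.

    The window ``[t, t + window_days - 1]`` is day-granular and inclusive at
    both ends; only windows anchored at an episode start need checking.
    """
    if window_days <= 0:
        raise ContractError("window_days must be positive")
    starts = [ep.start for ep in episodes]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ContractError("episodes must be ordered by start date")
    best = 0
    for i, anchor in enumerate(starts):
        limit = anchor + dt.timedelta(days=window_days - 1)
        count = sum(1 for s in starts[i:] if s <= limit)
        best = max(best, count)
    return best


def recurrent_documentation(
    diagnoses: Sequence,
    min_count: int,
    min_span_days: int,
    specialist_set: Iterable[str],
    specialist_min: int = 1,
) -> tuple[bool, list]:
    """Count/span/specialist rule for chronic inflammatory conditions.

    True iff there are at least ``min_count`` diagnoses, the first and last are
    at least ``min_span_days`` apart (inclusive comparison), and at least
    ``specialist_min`` of them were made by a provider in ``specialist_set``.
    Returns the verdict together with the qualifying diagnoses as evidence.
    """
    diagnoses = sorted(diagnoses, key=lambda d: d.date)
    specialist_set = set(specialist_set)
    if len(diagnoses) < min_count:
        return False, []
    span = (diagnoses[-1].date - diagnoses[0].date).days
    if span < min_span_days:
        return False, []
    n_specialist = sum(1 for d in diagnoses if d.provider_specialty in specialist_set)
    if n_specialist < specialist_min:
        return False, []
    return True, list(diagnoses)


def link_within(
    anchor_events: Sequence,
    other_events: Sequence,
    max_gap_days: int | None = None,
    *,
    days_before: int | None = None,
    days_after: int | None = None,
) -> list[tuple]:
    """All (anchor, other) pairs whose dates fall within the linkage window.

    With ``max_gap_days`` the window is symmetric, ``|date(a) - date(b)| <=
    max_gap_days``.  An asymmetric window may be given instead as
    ``days_before``/``days_after``: the other event must fall in
    ``[date(anchor) - days_before, date(anchor) + days_after]``.
    """
    if max_gap_days is not None:
        if max_gap_days < 0:
            raise ContractError("max_gap_days must be non-negative")
        days_before = days_after = max_gap_days
    if days_before is None or days_after is None:
        raise ContractError("provide max_gap_days or both days_before and days_after")
    pairs = []
    for a in anchor_events:
        lo = _date_of(a) - dt.timedelta(days=days_before)
        hi = _date_of(a) + dt.timedelta(days=days_after)
        for b in other_events:
            if lo <= _date_of(b) <= hi:
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Criterion combinator trees
# ---------------------------------------------------------------------------

_CONNECTIVES = {"and": " AND ", "or": " OR ", "and_or": " AND/OR "}


@dataclass(frozen=True)
class CriterionTree:
    """A leaf criterion (labeled A-E) or an AND / OR / AND-OR combination."""

    kind: str  # "leaf" | "and" | "or" | "and_or"
    label: Optional[str] = None
    children: tuple["CriterionTree", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "leaf":
            if not self.label:
                raise ValueError("leaf node requires a label")
            if self.children:
                raise ValueError("leaf node cannot have children")
        elif self.kind in _CONNECTIVES:
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires at least 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")
        labels = self.leaves()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique within one definition")

    @classmethod
    def leaf(cls, label: str) -> "CriterionTree":
        return cls(kind="leaf", label=label)

    @classmethod
    def from_spec(cls, spec) -> "CriterionTree":
        """Parse the nested-dict form used in the packaged rules file.

        A leaf is a bare label string; a combination is a one-key mapping
        ``{"and"|"or"|"and_or": [child, ...]}``.
        """
        if isinstance(spec, str):
            return cls.leaf(spec)
        if isinstance(spec, Mapping) and len(spec) == 1:
            (kind, children), = spec.items()
            return cls(kind=kind, children=tuple(cls.from_spec(c) for c in children))
        raise ValueError(f"malformed tree spec: {spec!r}")

    def leaves(self) -> list[str]:
        if self.kind == "leaf":
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def display(self) -> str:
        """Render with the ratified connective text, e.g. ``A AND (B AND/OR C)``."""
        if self.kind == "leaf":
            return self.label  # type: ignore[return-value]
        parts = [
            c.display() if c.kind == "leaf" else f"({c.display()})" for c in self.children
        ]
        return _CONNECTIVES[self.kind].join(parts)


def eval_tree(tree: CriterionTree, leaf_results: Mapping[str, bool]) -> bool:
    """Evaluate a criterion tree over per-leaf verdicts.

    ``and`` is conjunction; ``or`` and ``and_or`` are inclusive disjunction.
    A missing leaf verdict is a caller error naming the label.
    """
    if tree.kind == "leaf":
        if tree.label not in leaf_results:
            raise ContractError(f"missing verdict for criterion {tree.label!r}")
        return bool(leaf_results[tree.label])
    verdicts = (eval_tree(c, leaf_results) for c in tree.children)
    return all(verdicts) if tree.kind == "and" else any(verdicts)
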