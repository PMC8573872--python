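"""Modified-Delphi ballot tabulation and consensus classification.

The definitions were ratified by iterative anonymous yes/no voting: an
internal expert panel (n=8, three rounds) followed by an external panel
(n=5, two rounds).  Percent agreement is yes-votes over total votes, rounded
half-up to an integer percent; moderate consensus is 60-79% agreement and
strong consensus >=80%.  Definitions below 60% after a round are queued for
revision and resubmission in the next round.

The final per-panel agreement percentages for all 19 definitions ship as a
packaged fixture (``data/consensus_final_agreement.csv``), together with the
summary arithmetic over them (per-panel histograms; how many definitions were
strong in both panels).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ContractError, SequencingError

MODERATE_THRESHOLD = 60  # percent agreement
STRONG_THRESHOLD = 80

N_DEFINITIONS = 19


class ConsensusLevel(str, Enum):
    none = "none"
    moderate = "moderate"
    strong = "strong"


class Vote(BaseModel):
    model_config = ConfigDict(frozen=True)

    panelist_id: str
    vote: Literal["yes", "no"]
    comment: Optional[str] = None


class BallotRound(BaseModel):
    """One panel's votes on one definition in one round."""

    model_config = ConfigDict(frozen=True)

    panel: Literal["internal", "external"]
    round_index: int = Field(ge=1)
    aim_id: int = Field(ge=1, le=N_DEFINITIONS)
    votes: tuple[Vote, ...]

    @model_validator(mode="after")
    def _one_vote_per_panelist(self) -> "BallotRound":
        ids = [v.panelist_id for v in self.votes]
        if len(ids) != len(set(ids)):
            raise ValueError("each panelist may vote at most once per round per definition")
        return self


@dataclass(frozen=True)
class ConsensusReport:
    aim_id: int
    panel: str
    round_index: int
    n_votes: int
    n_yes: int
    agreement_pct: int
    level: ConsensusLevel


def agreement_percent(n_yes: int, n_votes: int) -> int:
    """Percent agreement, rounded half-up to the nearest integer.

    Exact integer arithmetic: floor(100*yes/n + 1/2) = (200*yes + n) // (2*n),
    so 7 of 8 gives 88 (87.5 rounds up).
    """
    if n_votes <= 0:
        raise ContractError("cannot tabulate zero ballots")
    if not 0 <= n_yes <= n_votes:
        raise ContractError("n_yes must be between 0 and n_votes")
    return (200 * n_yes + n_votes) // (2 * n_votes)


def classify_consensus(agreement_pct: int) -> ConsensusLevel:
    """Consensus level for an integer percent: <60 none, 60-79 moderate, >=80 strong."""
    if not 0 <= agreement_pct <= 100:
        raise ContractError("agreement_pct must lie in [0, 100]")
    if agreement_pct >= STRONG_THRESHOLD:
        return ConsensusLevel.strong
    if agreement_pct >= MODERATE_THRESHOLD:
        return ConsensusLevel.moderate
    return ConsensusLevel.none


def tabulate_round(ballot: BallotRound) -> ConsensusReport:
    """Tabulate one round's yes/no votes into a consensus report."""
    if not ballot.votes:
        raise ContractError("cannot tabulate a round with no votes")
    n_yes = sum(1 for v in ballot.votes if v.vote == "yes")
    pct = agreement_percent(n_yes, len(ballot.votes))
    return ConsensusReport(
        aim_id=ballot.aim_id,
        panel=ballot.panel,
        round_index=ballot.round_index,
        n_votes=len(ballot.votes),
        n_yes=n_yes,
        agreement_pct=pct,
        level=classify_consensus(pct),
    )


@dataclass
class RoundSequenceResult:
    """Per-definition trajectories plus the revision queue after each round."""

    reports: list[ConsensusReport]
    # (panel, round_index) -> aim_ids below the consensus threshold after that round
    revision_queue: dict[tuple[str, int], list[int]]
    # (panel, aim_id) -> final-round report for that panel
    terminal: dict[tuple[str, int], ConsensusReport]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "panel": r.panel,
                "round_index": r.round_index,
                "aim_id": r.aim_id,
                "n_votes": r.n_votes,
                "n_yes": r.n_yes,
                "agreement_pct": r.agreement_pct,
                "level": r.level.value,
            }
            for r in self.reports
        ]
        return pd.DataFrame(
            rows,
            columns=["panel", "round_index", "aim_id", "n_votes", "n_yes", "agreement_pct", "level"],
        )


def run_round_sequence(rounds: Iterable[BallotRound]) -> RoundSequenceResult:
    """Tabulate ordered rounds and derive the revision queue.

    Within each panel a definition's rounds must be contiguous from 1 (a gap
    raises :class:`SequencingError`).  After each round, definitions with
    agreement below the 60% consensus threshold are queued for revision and
    resubmission.
    """
    by_key: dict[tuple[str, int], list[BallotRound]] = {}
    for ballot in rounds:
        by_key.setdefault((ballot.panel, ballot.aim_id), []).append(ballot)

    reports: list[ConsensusReport] = []
    terminal: dict[tuple[str, int], ConsensusReport] = {}
    queue: dict[tuple[str, int], list[int]] = {}
    for (panel, aim_id), ballots in sorted(by_key.items()):
        ballots = sorted(ballots, key=lambda b: b.round_index)
        indices = [b.round_index for b in ballots]
        if indices != list(range(1, len(indices) + 1)):
            raise SequencingError(
                f"rounds for definition {aim_id} on the {panel} panel are not "
                f"contiguous from 1: {indices}"
            )
        for ballot in ballots:
            report = tabulate_round(ballot)
            reports.append(report)
            terminal[(panel, aim_id)] = report
            if report.agreement_pct < MODERATE_THRESHOLD:
                queue.setdefault((panel, ballot.round_index), []).append(aim_id)

    reports.sort(key=lambda r: (r.panel, r.round_index, r.aim_id))
    for key in queue:
        queue[key].sort()
    return RoundSequenceResult(reports=reports, revision_queue=queue, terminal=terminal)


# ---------------------------------------------------------------------------
# final-table summary
# ---------------------------------------------------------------------------

@dataclass
class FinalSummary:
    internal_histogram: dict[int, int]
    external_histogram: dict[int, int]
    strong_in_both: int
    not_strong_in_both: int


def load_final_agreement() -> pd.DataFrame:
    """The final percent-agreement table for the 19 definitions."""
    with (files("aimphenotype") / "data" / "consensus_final_agreement.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_final(table: pd.DataFrame | None = None) -> FinalSummary:
    """Summary counts over the final internal/external agreement percentages.

    Accepts any table with ``internal_final_pct`` and ``external_final_pct``
    columns and exactly one row per definition; defaults to the packaged
    fixture.
    """
    if table is None:
        table = load_final_agreement()
    if len(table) != N_DEFINITIONS:
        raise ContractError(f"expected {N_DEFINITIONS} rows, got {len(table)}")
    internal = [int(x) for x in table["internal_final_pct"]]
    external = [int(x) for x in table["external_final_pct"]]
    strong_both = sum(
        1
        for i, e in zip(internal, external)
        if classify_consensus(i) is ConsensusLevel.strong
        and classify_consensus(e) is ConsensusLevel.strong
    )
    return FinalSummary(
        internal_histogram=dict(sorted(Counter(internal).items())),
        external_histogram=dict(sorted(Counter(external).items())),
        strong_in_both=strong_both,
        not_strong_in_both=N_DEFINITIONS - strong_both,
    )


# ---------------------------------------------------------------------------
# ballots CSV I/O
# ---------------------------------------------------------------------------

def read_ballots(path: str | Path) -> list[BallotRound]:
    """Read ballots CSV (panel, round_index, aim_id, panelist_id, vote, comment)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"panel", "round_index", "aim_id", "panelist_id", "vote"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"ballots file is missing column(s): {', '.join(sorted(missing))}")
    rounds: dict[tuple, list[Vote]] = {}
    for _, row in df.iterrows():
        key = (row["panel"], int(row["round_index"]), int(row["aim_id"]))
        rounds.setdefault(key, []).append(
            Vote(
                panelist_id=row["panelist_id"],
                vote=row["vote"].strip().lower(),
                comment=row.get("comment") or None,
            )
        )
    return [
        BallotRound(panel=panel, round_index=idx, aim_id=aim, votes=tuple(votes))
        for (panel, idx, aim), votes in sorted(rounds.items())
    ]
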