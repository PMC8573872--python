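import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aimphenotype.definitions import default_registry
from aimphenotype.errors import ContractError
from aimphenotype.events import DiagnosisEvent
from aimphenotype.primitives import (
    CriterionTree,
    Episode,
    eval_tree,
    group_episodes,
    link_within,
    max_count_in_window,
    recurrent_documentation,
)

from .conftest import day

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def episodes_by_transitive_closure(dates, gap):
    """Union-find clustering over *all* pairs at most `gap` days apart."""
    dates = sorted(set(dates))
    parent = list(range(len(dates)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(dates)), 2):
        if abs((dates[j] - dates[i]).days) <= gap:
            parent[find(j)] = find(i)
    clusters = {}
    for i, d in enumerate(dates):
        clusters.setdefault(find(i), []).append(d)
    return sorted((min(c), max(c)) for c in clusters.values())


def max_in_window_by_day_scan(starts, window):
    """Exhaustively scan every candidate anchor day."""
    if not starts:
        return 0
    best = 0
    t = min(starts)
    while t <= max(starts):
        hi = t + dt.timedelta(days=window - 1)
        best = max(best, sum(1 for s in starts if t <= s <= hi))
        t += dt.timedelta(days=1)
    return best


def eval_by_expression(tree, assignment):
    """Render the tree to a Python boolean expression and eval it."""

    def render(node):
        if node.kind == "leaf":
            return f"assignment[{node.label!r}]"
        op = " and " if node.kind == "and" else " or "
        return "(" + op.join(render(c) for c in node.children) + ")"

    return eval(render(tree))


# ---------------------------------------------------------------------------
# episode grouping
# ---------------------------------------------------------------------------

dates_strategy = st.lists(
    st.integers(min_value=0, max_value=400).map(day), min_size=0, max_size=20
).map(sorted)


def test_group_episodes_basics():
    assert group_episodes([], 30) == []
    eps = group_episodes([day(0), day(10), day(60)], 30)
    assert [(e.start, e.end) for e in eps] == [(day(0), day(10)), (day(60), day(60))]
    (single,) = group_episodes([day(5)], 30)
    assert single.start == single.end == day(5)


def test_group_episodes_rejects_unsorted_input():
    with pytest.raises(ContractError):
        group_episodes([day(10), day(0)], 30)


@settings(derandomize=True, max_examples=200)
@given(dates=dates_strategy, gap=st.integers(min_value=1, max_value=60))
def test_group_episodes_matches_transitive_closure_oracle(dates, gap):
    got = [(e.start, e.end) for e in group_episodes(dates, gap)]
    assert got == episodes_by_transitive_closure(dates, gap)


@settings(derandomize=True, max_examples=100)
@given(dates=dates_strategy, gap=st.integers(min_value=1, max_value=60))
def test_group_episodes_idempotent_on_episode_starts(dates, gap):
    eps = group_episodes(dates, gap)
    regrouped = group_episodes([e.start for e in eps], gap)
    assert [e.start for e in regrouped] == [e.start for e in eps]


@settings(derandomize=True, max_examples=100)
@given(dates=dates_strategy, gap=st.integers(min_value=1, max_value=60))
def test_group_episodes_invariant_to_duplicates(dates, gap):
    doubled = sorted(dates + dates)
    a = [(e.start, e.end) for e in group_episodes(dates, gap)]
    b = [(e.start, e.end) for e in group_episodes(doubled, gap)]
    assert a == b


# ---------------------------------------------------------------------------
# rolling-window counting
# ---------------------------------------------------------------------------


def _episodes(*offsets):
    return [Episode(start=day(o), end=day(o)) for o in offsets]


def test_max_count_in_window_examples():
    assert max_count_in_window([], 365) == 0
    assert max_count_in_window(_episodes(0, 100, 200, 400), 365) == 3
    assert max_count_in_window(_episodes(0), 365) == 1


def test_window_is_closed_and_day_granular():
    # starts separated by exactly window-1 days fall in one window; by window, not
    assert max_count_in_window(_episodes(0, 364), 365) == 2
    assert max_count_in_window(_episodes(0, 365), 365) == 1


@settings(derandomize=True, max_examples=150)
@given(
    starts=st.lists(st.integers(min_value=0, max_value=600), min_size=0, max_size=12,
                    unique=True).map(sorted),
    window=st.integers(min_value=1, max_value=400),
)
def test_max_count_matches_exhaustive_day_scan(starts, window):
    eps = _episodes(*starts)
    assert max_count_in_window(eps, window) == max_in_window_by_day_scan(
        [day(s) for s in starts], window
    )


@settings(derandomize=True, max_examples=100)
@given(
    starts=st.lists(st.integers(min_value=0, max_value=600), min_size=0, max_size=12,
                    unique=True).map(sorted),
    window=st.integers(min_value=1, max_value=399),
)
def test_max_count_monotone_in_window_size(starts, window):
    eps = _episodes(*starts)
    assert max_count_in_window(eps, window) <= max_count_in_window(eps, window + 1)


# ---------------------------------------------------------------------------
# recurrent documentation
# ---------------------------------------------------------------------------


def _dx(offset, specialty="primary_care", concept="diabetes_type1"):
    return DiagnosisEvent(date=day(offset), concept=concept, provider_specialty=specialty)


def test_recurrent_documentation_examples():
    ok, ev = recurrent_documentation(
        [_dx(0, "endocrinology"), _dx(190)], 2, 183, {"endocrinology"}
    )
    assert ok and len(ev) == 2

    ok, _ = recurrent_documentation(
        [_dx(0, "endocrinology"), _dx(100)], 2, 183, {"endocrinology"}
    )
    assert not ok  # span 100 < 183

    ok, _ = recurrent_documentation([_dx(0), _dx(200)], 2, 183, {"endocrinology"})
    assert not ok  # no specialist


def test_recurrent_documentation_monotone_in_specialist_events():
    base = [_dx(0), _dx(200)]
    ok_before, _ = recurrent_documentation(base, 2, 183, {"endocrinology"})
    augmented = base + [_dx(90, "endocrinology")]
    ok_after, _ = recurrent_documentation(augmented, 2, 183, {"endocrinology"})
    assert not ok_before and ok_after


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def test_link_within_examples():
    assert link_within([], [day(1)], 14) == []
    pairs = link_within([day(10)], [day(0), day(30)], 14)
    assert pairs == [(day(10), day(0))]
    assert link_within([day(5)], [day(5), day(6)], 0) == [(day(5), day(5))]


@settings(derandomize=True, max_examples=100)
@given(
    anchors=st.lists(st.integers(0, 100).map(day), max_size=8),
    others=st.lists(st.integers(0, 100).map(day), max_size=8),
    gap=st.integers(0, 30),
)
def test_link_within_matches_brute_force_and_is_symmetric(anchors, others, gap):
    anchors, others = sorted(anchors), sorted(others)
    pairs = link_within(anchors, others, gap)
    brute = [(a, b) for a in anchors for b in others if abs((a - b).days) <= gap]
    assert pairs == brute
    transposed = {(b, a) for a, b in pairs}
    assert transposed == set(link_within(others, anchors, gap))


def test_link_within_asymmetric_window():
    pairs = link_within([day(10)], [day(8), day(9), day(12), day(14)],
                        days_before=1, days_after=3)
    assert [b for _, b in pairs] == [day(9), day(12)]


# ---------------------------------------------------------------------------
# criterion trees
# ---------------------------------------------------------------------------


def test_pneumonia_tree_evaluation():
    tree = CriterionTree.from_spec({"and": ["A", {"and_or": ["B", "C"]}]})
    assert eval_tree(tree, {"A": True, "B": False, "C": True})
    assert not eval_tree(tree, {"A": False, "B": True, "C": True})
    assert tree.display() == "A AND (B AND/OR C)"


def test_eval_tree_missing_leaf_names_label():
    tree = CriterionTree.from_spec({"and": ["A", "B"]})
    with pytest.raises(ContractError, match="'B'"):
        eval_tree(tree, {"A": True})


def test_tree_invariants_enforced():
    with pytest.raises(ValueError):
        CriterionTree.from_spec({"and": ["A"]})  # <2 children
    with pytest.raises(ValueError):
        CriterionTree.from_spec({"or": ["A", "A"]})  # duplicate labels


def test_all_registry_trees_match_truth_table_oracle(registry):
    """Every shipped tree equals expression-eval enumeration on all 2^k assignments."""
    for definition in registry.values():
        labels = definition.tree.leaves()
        for values in itertools.product([False, True], repeat=len(labels)):
            assignment = dict(zip(labels, values))
            assert eval_tree(definition.tree, assignment) == eval_by_expression(
                definition.tree, assignment
            ), f"definition {definition.aim_id}, assignment {assignment}"


def test_no_registry_tree_is_vacuously_true(registry):
    for definition in registry.values():
        all_false = {label: False for label in definition.tree.leaves()}
        assert not eval_tree(definition.tree, all_false)
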