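"""Full simulation pipeline: test-set construction, multi-network training,
word-by-word GPE scoring over critical regions, condition summaries and
across-network contrasts.

The design crosses four two-level factors — modifying position (matrix
subject vs object), RC type (SRC vs ORC), head-noun animacy and RC-noun
animacy — into 16 test conditions with a fixed number of novel token
sequences each.  Ten independently initialised networks play the role of
participants; effects are assessed by paired tests on per-network condition
means, and only effect *directions* are treated as replication criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mandarin_rc.grammar import (
    Category,
    Corpus,
    GrammarSpec,
    NOUN_CATEGORY,
    Sentence,
    TemplateSet,
    enumerate_templates,
    generate_corpus,
    sample_words,
)
from mandarin_rc.gpe import TargetOracle, gpe_trace
from mandarin_rc.srn import SRNConfig, init_network, train_on_corpus

__all__ = [
    "TestCondition",
    "TestItem",
    "ExperimentConfig",
    "ConditionSummary",
    "ContrastResult",
    "all_conditions",
    "build_test_set",
    "run_experiment",
    "summarize_conditions",
    "contrast_conditions",
    "paired_difference",
    "interaction_difference",
]

log = logging.getLogger("mandarin_rc")

CONDITION_COLUMNS = [
    "modifying_position", "rc_type", "head_animacy", "rc_noun_animacy",
]


@dataclass(frozen=True)
class TestCondition:
    """One cell of the 2 x 2 x 2 x 2 test design (intransitive SRCs excluded)."""

    modifying_position: str  # "subject" | "object"
    rc_type: str             # "SRC" | "ORC"
    head_animacy: str        # "ani" | "ina"
    rc_noun_animacy: str     # "ani" | "ina"


def all_conditions() -> list[TestCondition]:
    return [
        TestCondition(*combo)
        for combo in product(("subject", "object"), ("SRC", "ORC"),
                             ("ani", "ina"), ("ani", "ina"))
    ]


@dataclass(frozen=True)
class TestItem:
    """A concrete test sentence with its condition and critical positions.

    ``positions`` maps critical-region labels to 0-based token indices.
    Subject-modifying items are labelled W1/W2 (the RC opens the sentence);
    object-modifying items are labelled W3/W4 (the RC follows the matrix
    subject and verb), and their head noun ends the sentence so the position
    after the head is the end-of-sentence marker.
    """

    item_id: int
    sentence: Sentence
    condition: TestCondition
    positions: dict[str, int]


def _rc_categories(rc_type: str, rc_noun: str) -> tuple[Category, ...]:
    emb = NOUN_CATEGORY[rc_noun]
    if rc_type == "SRC":
        return (Category.VT, emb, Category.DE)
    if rc_type == "ORC":
        return (emb, Category.VT, Category.DE)
    raise ValueError(f"unknown RC type {rc_type!r}")


def _item_categories(
    condition: TestCondition, rng: np.random.Generator, grammar: GrammarSpec
) -> tuple[tuple[Category, ...], dict[str, int]]:
    """Category sequence and critical-position labels for one test item."""
    rc = _rc_categories(condition.rc_type, condition.rc_noun_animacy)
    head = NOUN_CATEGORY[condition.head_animacy]
    if condition.modifying_position == "subject":
        # RC + head open the sentence; a matrix VP drawn from the grammar
        # follows (restricted to bare-noun objects to keep items minimal).
        cats = rc + (head,)
        labels = {"W1": 0, "W2": 1, "DE": 2, "head": 3, "head+1": 4}
        if rng.random() < grammar.p_vp["vi"]:
            cats += (Category.VI,)
        else:
            cats += (Category.VT,)
            p_ani = grammar.object_np["ani"]
            p_ina = grammar.object_np["ina"]
            obj = "ani" if rng.random() < p_ani / (p_ani + p_ina) else "ina"
            cats += (NOUN_CATEGORY[obj],)
        cats += (Category.EOS,)
    else:
        # fixed animate subject + transitive verb, then the RC and its head,
        # which is the matrix object and ends the sentence
        cats = (Category.ANI_N, Category.VT) + rc + (head, Category.EOS)
        labels = {"W3": 2, "W4": 3, "DE": 4, "head": 5, "EOS": 6}
    return cats, labels


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full simulation."""

    n_networks: int = 10
    corpus_size: int = 10_000
    tokens_per_condition: int = 10
    master_seed: int = 0
    srn: SRNConfig = field(default_factory=SRNConfig)
    convention: str = "predict_next"
    shared_corpus: bool = False   # one corpus for all networks instead of one each
    max_item_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.tokens_per_condition < 1:
            raise ValueError("tokens_per_condition must be >= 1")


def build_test_set(
    grammar: GrammarSpec,
    config: ExperimentConfig,
    training_corpus: Corpus | Iterable[Corpus],
    seed: int | None = None,
) -> list[TestItem]:
    """Build the test items: ``tokens_per_condition`` per condition.

    Word tokens are sampled uniformly within category; any item whose token
    sequence occurs verbatim in the training corpus (or corpora) is
    resampled, so every item is novel for every network.  Raises
    ``RuntimeError`` if a novel item cannot be found within the retry bound.
    """
    corpora = [training_corpus] if isinstance(training_corpus, Corpus) else list(training_corpus)
    seen: set[tuple[int, ...]] = set()
    for corpus in corpora:
        seen |= corpus.token_sequences()
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    items: list[TestItem] = []
    used: set[tuple[int, ...]] = set()
    item_id = 0
    for condition in all_conditions():
        for _ in range(config.tokens_per_condition):
            for attempt in range(config.max_item_retries):
                cats, labels = _item_categories(condition, rng, grammar)
                tokens = sample_words(cats, rng)
                if tokens not in seen and tokens not in used:
                    break
            else:
                raise RuntimeError(
                    f"could not build a novel item for {condition} within "
                    f"{config.max_item_retries} attempts"
                )
            used.add(tokens)
            items.append(
                TestItem(item_id=item_id, sentence=Sentence(tokens=tokens),
                         condition=condition, positions=labels)
            )
            item_id += 1
    return items


def _critical_rows(
    item: TestItem, results, convention: str
) -> list[tuple[str, object]]:
    """Pair critical-position labels with the GPE results scored there.

    Labels whose position is not scored under the convention (the final EOS
    under ``predict_next``, the sentence-initial word under
    ``predict_current``) are omitted.
    """
    by_position = {r.position: r for r in results}
    rows = []
    for label, pos in item.positions.items():
        r = by_position.get(pos)
        if r is not None:
            rows.append((label, r))
    return rows


def run_experiment(
    config: ExperimentConfig,
    grammar: GrammarSpec | None = None,
    return_artifacts: bool = False,
):
    """Train ``n_networks`` seeded networks and score the full test set.

    Per network: a fresh training corpus is generated (unless
    ``shared_corpus``), the network is trained for one pass, and every test
    item is scored word by word.  Returns a tidy results table (one row per
    network x item x critical position); with ``return_artifacts`` also a
    dict holding the corpora, test items and trained states.  Fully
    reproducible from ``master_seed``.
    """
    grammar = grammar or GrammarSpec()
    templates = enumerate_templates(grammar)
    structural = enumerate_templates(grammar.structural_variant())
    oracle = TargetOracle(templates, structural)

    seed_rng = np.random.default_rng(config.master_seed)
    n_corpora = 1 if config.shared_corpus else config.n_networks
    corpus_seeds = seed_rng.integers(0, 2**31 - 1, size=n_corpora)
    net_seeds = seed_rng.integers(0, 2**31 - 1, size=config.n_networks)
    test_seed = int(seed_rng.integers(0, 2**31 - 1))

    log.info("generating %d corpus/corpora of %d sentences",
             n_corpora, config.corpus_size)
    corpora = [
        generate_corpus(grammar, config.corpus_size, int(s), templates)
        for s in corpus_seeds
    ]
    items = build_test_set(grammar, config, corpora, seed=test_seed)
    log.info("built %d test items (grammar %s)", len(items), grammar.hash())

    rows = []
    states = []
    for i in range(config.n_networks):
        corpus = corpora[0 if config.shared_corpus else i]
        state = init_network(config.srn, int(net_seeds[i]))
        _, record = train_on_corpus(state, corpus)
        log.info("network %d (seed %d): mean loss last 1000 sentences %.4f",
                 i, state.seed, record.mean_loss(last=1000))
        states.append(state)
        for item in items:
            results = gpe_trace(state, item.sentence, oracle,
                                convention=config.convention)
            for label, r in _critical_rows(item, results, config.convention):
                rows.append({
                    "network": i,
                    "network_seed": state.seed,
                    "item_id": item.item_id,
                    "modifying_position": item.condition.modifying_position,
                    "rc_type": item.condition.rc_type,
                    "head_animacy": item.condition.head_animacy,
                    "rc_noun_animacy": item.condition.rc_noun_animacy,
                    "position_label": label,
                    "position_index": r.position,
                    "hits": r.hits,
                    "false_alarms": r.false_alarms,
                    "misses": r.misses,
                    "gpe": r.gpe,
                    "convention": r.convention,
                })
    results_table = pd.DataFrame(rows)
    if return_artifacts:
        return results_table, {
            "corpora": corpora, "items": items, "states": states,
            "templates": templates, "oracle": oracle, "grammar": grammar,
        }
    return results_table


@dataclass
class ConditionSummary:
    """Condition x position means with across-network dispersion.

    ``table`` has one row per condition x position with the grand mean,
    the across-network standard error and the network count;
    ``per_network`` holds the underlying per-network means.
    """

    table: pd.DataFrame
    per_network: pd.DataFrame


def per_network_means(results: pd.DataFrame) -> pd.DataFrame:
    keys = ["network"] + CONDITION_COLUMNS + ["position_label"]
    return results.groupby(keys, as_index=False)["gpe"].mean()


def summarize_conditions(results: pd.DataFrame) -> ConditionSummary:
    """Mean GPE per condition x position, with across-network standard errors."""
    if results.empty:
        raise ValueError("empty results table")
    per_net = per_network_means(results)
    keys = CONDITION_COLUMNS + ["position_label"]
    grouped = per_net.groupby(keys)["gpe"]
    table = grouped.agg(
        mean_gpe="mean",
        sd_networks="std",
        n_networks="count",
    ).reset_index()
    table["se"] = table["sd_networks"] / np.sqrt(table["n_networks"])
    return ConditionSummary(table=table, per_network=per_net)


@dataclass
class ContrastResult:
    """A paired across-network contrast at one word position."""

    name: str
    position: str
    per_network: np.ndarray     # one paired difference per network
    mean_diff: float
    effect_size: float          # Cohen's d of the paired differences
    t: float
    p_t: float
    n_positive: int
    n_negative: int
    p_sign: float
    degenerate: bool            # zero variance across networks

    @property
    def direction(self) -> int:
        """Sign of the mean difference (+1, -1 or 0)."""
        return int(np.sign(self.mean_diff))


def _paired_result(name: str, position: str, diffs: np.ndarray) -> ContrastResult:
    diffs = np.asarray(diffs, dtype=float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    degenerate = sd == 0.0
    if degenerate:
        t_stat, p_t = (np.nan, np.nan) if mean == 0.0 else (np.inf, 0.0)
        d = np.nan
    else:
        t_stat, p_t = stats.ttest_1samp(diffs, 0.0)
        d = mean / sd
    n_pos = int((diffs > 0).sum())
    n_neg = int((diffs < 0).sum())
    n = n_pos + n_neg
    p_sign = float(stats.binomtest(n_pos, n, 0.5).pvalue) if n else 1.0
    return ContrastResult(
        name=name, position=position, per_network=diffs, mean_diff=mean,
        effect_size=float(d), t=float(t_stat), p_t=float(p_t),
        n_positive=n_pos, n_negative=n_neg, p_sign=p_sign,
        degenerate=degenerate,
    )


def _position_means(
    results: pd.DataFrame, position: str, where: Mapping[str, str] | None = None
) -> pd.DataFrame:
    sub = results[results["position_label"] == position]
    if where:
        for col, val in where.items():
            sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"no rows at position {position!r} with filter {where}")
    return sub


def paired_difference(
    results: pd.DataFrame,
    position: str,
    factor: str,
    level_a: str,
    level_b: str,
    where: Mapping[str, str] | None = None,
    name: str | None = None,
) -> ContrastResult:
    """Across-network paired difference ``mean(level_a) - mean(level_b)``.

    Each network contributes one pair: its mean GPE over all items at
    ``position`` on each level of ``factor`` (after optional filtering).
    """
    sub = _position_means(results, position, where)
    means = sub.groupby(["network", factor])["gpe"].mean().unstack(factor)
    diffs = (means[level_a] - means[level_b]).to_numpy()
    label = name or f"{factor}:{level_a}-{level_b}" + (f"|{where}" if where else "")
    return _paired_result(label, position, diffs)


def interaction_difference(
    results: pd.DataFrame,
    position: str,
    factor: str,
    level_a: str,
    level_b: str,
    across: str,
    across_a: str,
    across_b: str,
    name: str | None = None,
) -> ContrastResult:
    """Difference-of-differences: the simple effect of ``factor`` computed
    within ``across = across_a`` minus the same effect within
    ``across = across_b``, paired by network."""
    sub = _position_means(results, position)
    means = sub.groupby(["network", across, factor])["gpe"].mean()
    diffs = []
    for net in sorted(sub["network"].unique()):
        eff_a = means[net, across_a, level_a] - means[net, across_a, level_b]
        eff_b = means[net, across_b, level_a] - means[net, across_b, level_b]
        diffs.append(eff_a - eff_b)
    label = name or f"({factor}:{level_a}-{level_b}) x ({across}:{across_a}-{across_b})"
    return _paired_result(label, position, np.asarray(diffs))


def contrast_conditions(
    results: pd.DataFrame, position: str = "head"
) -> dict[str, ContrastResult]:
    """The named contrasts at one position.

    Main effects of RC type, head animacy and RC-noun animacy; the simple
    RC-type effects at each modifying position; and the RC-type x modifying
    position and head-animacy x modifying-position interactions.  Contrasts
    whose cells do not exist at the position (e.g. interactions at positions
    scored for only one modifying position) are omitted.
    """
    out: dict[str, ContrastResult] = {}

    def add(key: str, fn, *args, **kwargs) -> None:
        try:
            out[key] = fn(results, position, *args, **kwargs)
        except (ValueError, KeyError):
            pass

    add("rc_type", paired_difference, "rc_type", "SRC", "ORC",
        name="rc_type SRC-ORC")
    add("head_animacy", paired_difference, "head_animacy", "ani", "ina",
        name="head_animacy ani-ina")
    add("rc_noun_animacy", paired_difference, "rc_noun_animacy", "ani", "ina",
        name="rc_noun_animacy ani-ina")
    for pos_level in ("subject", "object"):
        add(f"rc_type@{pos_level}", paired_difference, "rc_type", "SRC", "ORC",
            where={"modifying_position": pos_level},
            name=f"rc_type SRC-ORC | {pos_level}-modifying")
        add(f"head_animacy@{pos_level}", paired_difference,
            "head_animacy", "ani", "ina",
            where={"modifying_position": pos_level},
            name=f"head_animacy ani-ina | {pos_level}-modifying")
    add("rc_type_x_position", interaction_difference, "rc_type", "SRC", "ORC",
        "modifying_position", "subject", "object",
        name="rc_type x modifying_position")
    add("head_animacy_x_position", interaction_difference,
        "head_animacy", "ani", "ina",
        "modifying_position", "subject", "object",
        name="head_animacy x modifying_position")
    return out


def plot_condition_summary(summary: ConditionSummary, out_dir) -> list[str]:
    """Word-by-word mean GPE figures, one panel per RC type and modifying
    position (requires matplotlib; returns the written file paths)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order_subject = ["W1", "W2", "DE", "head", "head+1"]
    order_object = ["W3", "W4", "DE", "head", "EOS"]
    written = []
    for mod_pos, order in (("subject", order_subject), ("object", order_object)):
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, rc_type in zip(axes, ("SRC", "ORC")):
            sub = summary.table[
                (summary.table["modifying_position"] == mod_pos)
                & (summary.table["rc_type"] == rc_type)
            ]
            for (head_a, rcn_a), grp in sub.groupby(
                ["head_animacy", "rc_noun_animacy"]
            ):
                grp = grp.set_index("position_label").reindex(order).dropna()
                ax.errorbar(grp.index, grp["mean_gpe"], yerr=grp["se"],
                            marker="o", capsize=2,
                            label=f"{rcn_a}RCN+{head_a}Head")
            ax.set_title(f"{mod_pos}-modifying {rc_type}")
            ax.set_ylabel("mean GPE")
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"gpe_{mod_pos}_modifying.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))
    return written
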