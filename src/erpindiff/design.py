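"""Stimulus-list construction for the grammaticality judgment task.

The experiment crosses Grammaticality (agreeing vs disagreeing postnominal
adjective) with noun Markedness (masculine vs feminine), giving four
experimental conditions.  900 sentences are split over three lists: each list
carries 160 experimental gender trials (40 per condition) and 80 items from an
unrelated study, both unique to the list, plus 150 fillers and 30
determiner-noun violation sentences shared by all lists - 420 sentences per
list, 720 list-unique sentences overall.  Experimental nouns are inanimate and
half of each condition has a transparent gender ending (-o / -a).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from erpindiff.epochs import EXPERIMENTAL_CONDITIONS

N_LISTS = 3
TRIALS_PER_CONDITION = 40
N_OTHER_STUDY = 80
N_FILLERS = 150
N_DET_NOUN_VIOLATIONS = 30

SENTENCE_COLUMNS = [
    "item_id", "condition", "noun_transparency", "target_word_index", "inanimate",
]


@dataclass
class StimulusDesign:
    """One presentation list: ``list_id`` in 1..3 plus its sentence table."""

    list_id: int
    sentences: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.sentences["condition"].value_counts()

    @property
    def n_experimental(self) -> int:
        return int(self.sentences["condition"].isin(EXPERIMENTAL_CONDITIONS).sum())

    def experimental(self) -> pd.DataFrame:
        return self.sentences[self.sentences["condition"].isin(EXPERIMENTAL_CONDITIONS)].reset_index(drop=True)


def _sentence_block(rng: np.random.Generator, item_ids: list[str], condition: str,
                    experimental: bool) -> pd.DataFrame:
    n = len(item_ids)
    if experimental:
        # half transparent / half opaque noun endings within each condition
        transparency = np.array(["transparent"] * (n // 2) + ["opaque"] * (n - n // 2))
        rng.shuffle(transparency)
    else:
        transparency = np.full(n, "n/a")
    return pd.DataFrame(
        {
            "item_id": item_ids,
            "condition": condition,
            "noun_transparency": transparency,
            # adjective position within the RSVP stream (word index, 1-based)
            "target_word_index": rng.integers(4, 9, size=n),
            "inanimate": experimental,
        }
    )


def build_lists(seed: int) -> list[StimulusDesign]:
    """Build the three presentation lists; deterministic for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    shared = [
        _sentence_block(rng, [f"FIL{i:03d}" for i in range(1, N_FILLERS + 1)], "filler", False),
        _sentence_block(
            rng,
            [f"DNV{i:03d}" for i in range(1, N_DET_NOUN_VIOLATIONS + 1)],
            "det_noun_violation",
            False,
        ),
    ]
    designs = []
    for list_id in range(1, N_LISTS + 1):
        blocks = []
        for cond in EXPERIMENTAL_CONDITIONS:
            ids = [
                f"L{list_id}_{cond}_{i:02d}" for i in range(1, TRIALS_PER_CONDITION + 1)
            ]
            blocks.append(_sentence_block(rng, ids, cond, True))
        blocks.append(
            _sentence_block(
                rng,
                [f"L{list_id}_OTH{i:02d}" for i in range(1, N_OTHER_STUDY + 1)],
                "other_study",
                False,
            )
        )
        sentences = pd.concat(blocks + shared, ignore_index=True)
        order = rng.permutation(len(sentences))
        designs.append(StimulusDesign(list_id=list_id, sentences=sentences.iloc[order].reset_index(drop=True)))
    return designs


def total_unique_sentences(designs: list[StimulusDesign]) -> int:
    """Number of distinct sentences across all lists (shared items counted once)."""
    return len(set().union(*(set(d.sentences["item_id"]) for d in designs)))


def list_unique_sentences(designs: list[StimulusDesign]) -> int:
    """Number of sentences that occur in exactly one list."""
    ids = pd.concat([d.sentences["item_id"] for d in designs])
    counts = ids.value_counts()
    return int((counts == 1).sum())
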