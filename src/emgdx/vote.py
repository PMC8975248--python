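"""Boyer-Moore majority vote over the per-downsample labels of a signal.

The M class labels that the classifier assigns to the M downsampled
children of one recording form a sequence; the recording's class is the
label occupying a *strict* majority (> M/2) of that sequence, if one
exists.  Boyer-Moore finds the only possible candidate in one pass with
O(1) extra state; a second pass verifies the strict majority.  When no
label reaches a strict majority the recording is assigned the explicit
INDETERMINATE outcome — there is no plurality fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LabelSequence:
    parent_id: str
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("label sequence must be non-empty")


@dataclass(frozen=True)
class VoteResult:
    parent_id: str
    decision: str  # a class label, or INDETERMINATE
    majority_count: int


def bmmv(sequence: LabelSequence | Sequence[str], parent_id: str = "") -> VoteResult:
    """Majority decision for one label sequence.

    Pass 1 keeps a candidate and a counter (increment on match, decrement
    on mismatch, reseat when the counter hits zero); pass 2 counts the
    candidate's occurrences and demands count > M/2.
    """
    if isinstance(sequence, LabelSequence):
        labels = sequence.labels
        parent_id = sequence.parent_id
    else:
        labels = tuple(sequence)
    if len(labels) == 0:
        raise ValueError("label sequence must be non-empty")

    candidate = None
    counter = 0
    for lab in labels:
        if counter == 0:
            candidate, counter = lab, 1
        elif lab == candidate:
            counter += 1
        else:
            counter -= 1

    count = sum(1 for lab in labels if lab == candidate)
    if 2 * count > len(labels):
        return VoteResult(parent_id=parent_id, decision=candidate, majority_count=count)
    return VoteResult(parent_id=parent_id, decision=INDETERMINATE, majority_count=count)
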