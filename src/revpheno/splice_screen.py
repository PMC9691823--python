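"""Screen rare variants for predicted splice-disrupting effects.

Operates on variants that already passed the rarity filter, using the four
precomputed splice delta scores carried on each record (acceptor gain,
acceptor loss, donor gain, donor loss — the standard deep-learning splice
predictor output).  A variant is a splice candidate when its maximum delta
strictly exceeds the cut-off (default 0.5, the predictor's recommended
high-precision threshold) and it has not already been asserted benign.
This is the route by which deep-intronic and synonymous variants — which
no consequence-based prioritisation class would catch — can enter the
diagnostic analysis.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .snv_prioritizer import AnnotatedVariant, ThresholdConfig

logger = logging.getLogger(__name__)

__all__ = ["splice_candidates"]


def splice_candidates(
    variants: Iterable[AnnotatedVariant], t: ThresholdConfig | None = None
) -> list[AnnotatedVariant]:
    """Variants predicted to affect splicing; order preserved.

    Retained iff ``max(splice_deltas) > splice_delta_min`` (strict) and the
    clinical-significance assertion is not benign (by default likely-benign
    assertions are excluded too; set
    ``ThresholdConfig(splice_exclude_likely_benign=False)`` to exclude only
    outright 'benign').  Variants with no delta scores are not retained.
    """
    t = t or ThresholdConfig()
    excluded_clinsig = {"benign"}
    if t.splice_exclude_likely_benign:
        excluded_clinsig.add("likely_benign")

    out: list[AnnotatedVariant] = []
    n_unscored = 0
    for v in variants:
        if v.splice_deltas is None:
            n_unscored += 1
            continue
        if max(v.splice_deltas) > t.splice_delta_min and v.clinsig not in excluded_clinsig:
            out.append(v)
    if n_unscored:
        logger.info("%d variants lacked splice delta scores", n_unscored)
    return out
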