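"""Reference-gene (spike-in) selection and ground-truth construction.

ERCC spike-ins are 92 synthetic RNA controls added to each sample at a
constant concentration, making them external reference genes: after a
correct global scaling their levels are equal across samples.  This
module locates spike-in rows in a count matrix by ID prefix, filters them
by a minimum-detection threshold (a spike-in must reach at least ``t``
reads in *every* sample to be a reliable reference), and builds the
ground-truth normalization by scaling against the survivors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import InsufficientReferencesError
from .normalize import NormalizationResult, apply_factors, reference_factors

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSelectionConfig:
    """Detection threshold and ID pattern for spike-in selection."""

    min_count_threshold: int = 10
    id_pattern: str = "ERCC-"
    use_regex: bool = False

    def __post_init__(self):
        if self.min_count_threshold < 1:
            raise ValueError("min_count_threshold must be >= 1")


def ercc_ids() -> list[str]:
    """The canonical list of 92 ERCC control identifiers."""
    text = resources.files("cdev").joinpath("data/ercc_ids.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def detect_spikein_rows(
    Y: pd.DataFrame,
    id_pattern: str = "ERCC-",
    use_regex: bool = False,
) -> list[str]:
    """Gene IDs matching the spike-in pattern (exact, case-sensitive prefix).

    ``use_regex=True`` treats ``id_pattern`` as a regular expression
    matched from the start of the ID, for non-ERCC spike-in schemes.  An
    empty result is allowed but logged.
    """
    ids = Y.index.astype(str)
    if use_regex:
        rx = re.compile(id_pattern)
        hits = [g for g in ids if rx.match(g)]
    else:
        hits = [g for g in ids if g.startswith(id_pattern)]
    if not hits:
        logger.warning("no gene ID matches spike-in pattern %r", id_pattern)
    return hits


def select_references(
    Y: pd.DataFrame,
    candidates,
    min_count: int = 10,
) -> tuple[list[str], pd.Series]:
    """Keep candidates detected with at least ``min_count`` reads everywhere.

    Returns the surviving IDs plus each candidate's minimum count across
    samples, useful for exploring the retention/threshold trade-off.
    Raises when nothing survives, reporting the largest threshold that
    would still retain at least one candidate.
    """
    cand = pd.Index(list(candidates)).astype(str)
    if cand.empty:
        raise InsufficientReferencesError("empty candidate set")
    missing = cand.difference(Y.index)
    if not missing.empty:
        raise InsufficientReferencesError(
            f"{len(missing)} candidate IDs absent from the matrix"
        )
    minima = Y.loc[cand].min(axis=1).astype(float)
    kept = minima.index[minima >= min_count].tolist()
    if not kept:
        best = int(minima.max())
        raise InsufficientReferencesError(
            f"no candidate reaches {min_count} reads in every sample; "
            f"the largest usable threshold is t = {best}"
        )
    return kept, minima


def ground_truth_matrix(
    Y: pd.DataFrame,
    references,
) -> tuple[pd.DataFrame, NormalizationResult]:
    """Scale ``Y`` against its references to obtain the ground truth.

    Returns ``A`` (the reference-scaled matrix, with reference sums
    exactly equalized across samples) and the scaling factors.
    """
    result = reference_factors(Y, references)
    return apply_factors(Y, result.factors), result
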