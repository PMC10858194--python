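"""Inverted-repeat scanning and scoring.

Dimeric bacterial repressors typically bind palindromic operators: two
half-sites where one is the reverse complement of the other, separated by a
short spacer.  This module scans an inter-operon region for the
highest-scoring inverted repeat (the *seed operator*) under the score

    s = w_match * x_m + w_mismatch * y + p

where ``x_m`` counts arm positions that are reverse-complementary, ``y``
counts those that are not, and ``p`` is a banded spacer (gap) adjustment:
spacers 0-4 bases earn +4, 5-6 +2, 7-8 0, 9-10 -2, 11-12 -4, 13-14 -6,
15-16 -8, 17-18 -10.

The default weights are +2 per match and -2 per mismatch, so the score
favors long, well-paired arms while tolerating imperfect ones.  A
literal-print mode with +2 for mismatches as well is kept behind
:meth:`RepeatScoreParams.literal_paper` for comparison; under that
convention every equal-length arm pairing scores identically, which defeats
repeat detection, so it is not the default.

``find_best_inverted_repeat`` is a vectorized scan over (arm length, spacer,
offset); ``enumerate_all_repeats`` is the deliberately naive exhaustive
oracle used by the tests (and the verbose report).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from typing import Optional

import numpy as np

from .context import InterOperonRegion, reverse_complement
from .errors import NoRepeatFoundError, SpacerTooLargeError, UnequalArmLengthError

# (low, high, adjustment) bands for the spacer between half-sites
DEFAULT_GAP_TABLE: tuple[tuple[int, int, int], ...] = (
    (0, 4, 4),
    (5, 6, 2),
    (7, 8, 0),
    (9, 10, -2),
    (11, 12, -4),
    (13, 14, -6),
    (15, 16, -8),
    (17, 18, -10),
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepeatScoreParams:
    """Weights and scan bounds for inverted-repeat scoring."""

    match_weight: int = 2
    mismatch_weight: int = -2
    gap_table: tuple[tuple[int, int, int], ...] = DEFAULT_GAP_TABLE
    min_arm: int = 4
    max_arm: int = 20
    max_spacer: int = 18
    spacer_overflow_policy: str = "forbid"  # or "extrapolate"
    score_floor: Optional[int] = None  # None -> match_weight * min_arm

    def __post_init__(self):
        if self.min_arm < 2:
            raise ValueError("min_arm must be >= 2")
        if self.spacer_overflow_policy not in ("forbid", "extrapolate"):
            raise ValueError("spacer_overflow_policy must be forbid|extrapolate")

    @classmethod
    def literal_paper(cls, **overrides) -> "RepeatScoreParams":
        """The as-printed convention that rewards mismatches like matches."""
        overrides.setdefault("mismatch_weight", 2)
        return cls(**overrides)

    @property
    def effective_floor(self) -> int:
        # score of a perfect min_arm repeat at the worst zero-adjustment spacer
        if self.score_floor is not None:
            return self.score_floor
        return self.match_weight * self.min_arm


@dataclass(frozen=True)
class InvertedRepeat:
    """A scored candidate operator: two arms, a spacer, and the score parts.

    Coordinates are 0-based half-open positions on the scanned region.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    spacer: int
    matches: int
    mismatches: int
    gap_adjustment: int
    score: int
    sequence: str

    @property
    def arm_length(self) -> int:
        return self.left_end - self.left_start

    @property
    def length(self) -> int:
        """Total operator length: both arms plus the spacer."""
        return self.right_end - self.left_start

    def sort_key(self) -> tuple:
        """Ordering key: higher score, then longer arms, smaller spacer, leftmost."""
        return (-self.score, -self.arm_length, self.spacer, self.left_start)


@dataclass(frozen=True)
class SeedOperator:
    """The argmax inverted repeat of a region, with provenance."""

    repeat: InvertedRepeat
    contig_id: str = ""
    region_start: int = 0
    region_end: int = 0


def gap_adjustment(spacer: int, params: RepeatScoreParams = RepeatScoreParams()) -> int:
    """Banded spacer adjustment p; see the table in the module docstring.

    Beyond the table (> max band) the 'extrapolate' policy continues the
    -2-per-2-bases progression; 'forbid' raises.
    """
    if spacer < 0:
        raise ValueError("spacer must be non-negative")
    for lo, hi, p in params.gap_table:
        if lo <= spacer <= hi:
            return p
    top = max(hi for _, hi, _ in params.gap_table)
    if params.spacer_overflow_policy == "forbid":
        raise SpacerTooLargeError(
            f"spacer {spacer} exceeds the gap table (max {top})"
        )
    floor_p = min(p for _, _, p in params.gap_table)
    return floor_p - 2 * ceil((spacer - top) / 2)


def score_repeat(
    left_arm_seq: str,
    right_arm_seq: str,
    spacer: int,
    params: RepeatScoreParams = RepeatScoreParams(),
) -> tuple[int, int, int, int]:
    """Score one arm pairing; returns (matches, mismatches, p, s).

    Position ``k`` of the left arm pairs with position ``L-1-k`` of the right
    arm; it is a match when the two bases are reverse-complementary.  N never
    matches.
    """
    if len(left_arm_seq) != len(right_arm_seq):
        raise UnequalArmLengthError(
            f"arm lengths differ: {len(left_arm_seq)} vs {len(right_arm_seq)}"
        )
    left = left_arm_seq.upper()
    right_rc = reverse_complement(right_arm_seq.upper())
    matches = sum(
        1 for a, b in zip(left, right_rc) if a == b and a in _COMP
    )
    mismatches = len(left) - matches
    p = gap_adjustment(spacer, params)
    s = params.match_weight * matches + params.mismatch_weight * mismatches + p
    return matches, mismatches, p, s


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode a sequence and its positionwise complement.

    Ambiguous bases complement to a sentinel that equals nothing, so they
    always count as mismatches.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    comp = np.full_like(arr, ord("0"))
    for a, b in _COMP.items():
        comp[arr == ord(a)] = ord(b)
    return arr, comp


def _repeat_at(seq: str, offset: int, arm: int, spacer: int,
               params: RepeatScoreParams) -> InvertedRepeat:
    ls, le = offset, offset + arm
    rs, re_ = le + spacer, le + spacer + arm
    m, mm, p, s = score_repeat(seq[ls:le], seq[rs:re_], spacer, params)
    return InvertedRepeat(
        left_start=ls, left_end=le, right_start=rs, right_end=re_,
        spacer=spacer, matches=m, mismatches=mm, gap_adjustment=p,
        score=s, sequence=seq[ls:re_].upper(),
    )


def find_best_inverted_repeat(
    region: "InterOperonRegion | str",
    params: RepeatScoreParams = RepeatScoreParams(),
) -> SeedOperator:
    """Highest-scoring inverted repeat over all (arm, spacer, offset).

    Deterministic tie-break: longer arms first, then smaller spacer, then
    leftmost start.  Raises :class:`NoRepeatFoundError` when nothing reaches
    the score floor (default: a perfect minimum-length repeat with a
    zero-adjustment spacer).
    """
    if isinstance(region, InterOperonRegion):
        seq = region.sequence
        provenance = (region.contig_id, region.start, region.end)
    else:
        seq = str(region)
        provenance = ("", 0, len(seq))

    L = len(seq)
    if L < 2 * params.min_arm:
        raise NoRepeatFoundError(
            f"region length {L} < 2 * min_arm ({2 * params.min_arm})"
        )

    arr, comp = _encode(seq)
    mw, ww = params.match_weight, params.mismatch_weight

    best: Optional[tuple[int, int, int, int]] = None  # (score, arm, spacer, offset)
    # arm descending, spacer ascending, offset ascending == tie-break order,
    # so a strictly-greater update realizes the deterministic argmax
    for arm in range(min(params.max_arm, L // 2), params.min_arm - 1, -1):
        for spacer in range(0, min(params.max_spacer, L - 2 * arm) + 1):
            n_off = L - 2 * arm - spacer + 1
            if n_off <= 0:
                continue
            p = gap_adjustment(spacer, params)
            matches = np.zeros(n_off, dtype=np.int32)
            shift = 2 * arm + spacer - 1
            for k in range(arm):
                matches += (
                    arr[k : k + n_off] == comp[shift - k : shift - k + n_off]
                ).astype(np.int32)
            scores = mw * matches + ww * (arm - matches) + p
            i = int(np.argmax(scores))  # first max == leftmost
            if best is None or int(scores[i]) > best[0]:
                best = (int(scores[i]), arm, spacer, i)

    if best is None or best[0] < params.effective_floor:
        raise NoRepeatFoundError(
            f"no inverted repeat reached the score floor "
            f"({params.effective_floor}) in a {L} bp region"
        )

    _, arm, spacer, offset = best
    rep = _repeat_at(seq, offset, arm, spacer, params)
    return SeedOperator(
        repeat=rep,
        contig_id=provenance[0],
        region_start=provenance[1],
        region_end=provenance[2],
    )


def enumerate_all_repeats(
    region_seq: str, params: RepeatScoreParams = RepeatScoreParams()
) -> list[InvertedRepeat]:
    """Exhaustive O(L^2 * arm_max) enumeration of every candidate repeat.

    The brute-force oracle: a superset containing the find_best result.
    Returned sorted best-first under the tie-break order.
    """
    seq = str(region_seq)
    L = len(seq)
    out: list[InvertedRepeat] = []
    for arm in range(params.min_arm, min(params.max_arm, L // 2) + 1):
        for spacer in range(0, min(params.max_spacer, L - 2 * arm) + 1):
            for offset in range(0, L - 2 * arm - spacer + 1):
                out.append(_repeat_at(seq, offset, arm, spacer, params))
    out.sort(key=InvertedRepeat.sort_key)
    return out


def best_repeat_score(
    seq: str, params: RepeatScoreParams = RepeatScoreParams()
) -> Optional[int]:
    """Best inverted-repeat score within ``seq``, or None if unscannable.

    Ignores the score floor — used to compare repeat quality of short
    sequences (e.g. consensus vs. individual instances).
    """
    try:
        no_floor = replace(params, score_floor=-(10**9))
        return find_best_inverted_repeat(seq, no_floor).repeat.score
    except NoRepeatFoundError:
        return None
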