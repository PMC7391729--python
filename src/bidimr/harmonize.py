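"""Allele harmonization of exposure instruments with outcome statistics.

For each instrument present in the outcome table the outcome effect is
re-expressed per copy of the exposure's effect allele.  Resolution order:
same allele pair (possibly with swapped orientation), then strand
complement, then the palindromic policy; anything irreconcilable is
dropped with a reason.  Dropped SNPs never reach the estimators but are
always logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .instruments import InstrumentSet
from .sumstats import SnpRecord, SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# statuses of retained pairs; compound strand+sign case kept distinct so the
# status alone determines the transformation applied
STATUS_ALIGNED = "aligned"
STATUS_SIGN_FLIPPED = "sign_flipped"
STATUS_STRAND_FLIPPED = "strand_flipped"
STATUS_STRAND_SIGN_FLIPPED = "strand_sign_flipped"
STATUS_PALINDROMIC_KEPT = "palindromic_kept"

DROP_MISSING = "missing"
DROP_MISMATCH = "mismatch"
DROP_PALINDROMIC = "palindromic"
DROP_AMBIGUOUS = "ambiguous"

PALINDROME_POLICIES = ("drop_all", "infer_by_eaf", "keep_as_is")
DEFAULT_EAF_WINDOW = 0.08


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """A/T or G/C pairs: strand is unresolvable from allele labels."""
    return COMPLEMENT[allele_a] == allele_b


@dataclass(frozen=True, slots=True)
class HarmonizedPair:
    """Allele-aligned effect quadruple for one instrument."""

    rsid: str
    bx: float
    sx: float
    by: float
    sy: float
    status: str

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


@dataclass(frozen=True)
class HarmonizedPairs:
    """Harmonization result: retained pairs plus a drop log.

    Invariant: retained + dropped counts add up to the number of
    instruments seen (instruments missing from the outcome table are
    dropped with reason ``missing``).
    """

    exposure_id: str
    outcome_id: str
    pairs: tuple[HarmonizedPair, ...]
    drop_log: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        rsids = [p.rsid for p in self.pairs]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsid among harmonized pairs")
        overlap = set(rsids) & set(self.drop_log)
        if overlap:
            raise ValueError(f"rsids both retained and dropped: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[HarmonizedPair]:
        return iter(self.pairs)

    @property
    def n_dropped(self) -> int:
        return len(self.drop_log)


def _minor_side(eaf: float) -> bool:
    """True when the effect allele is the minor one."""
    return eaf < 0.5


def _harmonize_one(
    exp: SnpRecord,
    out: SnpRecord,
    policy: str,
    eaf_window: float,
) -> tuple[HarmonizedPair | None, str | None]:
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    by, o_eaf = out.beta, out.eaf

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return None, DROP_MISMATCH
        if policy == "drop_all":
            return None, DROP_PALINDROMIC
        # label-based orientation first
        if o_ea != e_ea:
            by = -by
            o_eaf = None if o_eaf is None else 1.0 - o_eaf
        if policy == "infer_by_eaf":
            lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
            if (
                exp.eaf is None
                or o_eaf is None
                or lo <= exp.eaf <= hi
                or lo <= o_eaf <= hi
            ):
                return None, DROP_AMBIGUOUS
            # labels agree but frequencies sit on opposite sides of 0.5:
            # the outcome is on the other strand with swapped orientation
            if _minor_side(exp.eaf) != _minor_side(o_eaf):
                by = -by
        return (
            HarmonizedPair(exp.rsid, exp.beta, exp.se, by, out.se, STATUS_PALINDROMIC_KEPT),
            None,
        )

    if (o_ea, o_oa) == (e_ea, e_oa):
        status = STATUS_ALIGNED
    elif (o_ea, o_oa) == (e_oa, e_ea):
        by = -by
        status = STATUS_SIGN_FLIPPED
    else:
        c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        if (c_ea, c_oa) == (e_ea, e_oa):
            status = STATUS_STRAND_FLIPPED
        elif (c_ea, c_oa) == (e_oa, e_ea):
            by = -by
            status = STATUS_STRAND_SIGN_FLIPPED
        else:
            return None, DROP_MISMATCH
    return HarmonizedPair(exp.rsid, exp.beta, exp.se, by, out.se, status), None


def harmonize(
    instruments: InstrumentSet,
    outcome: SummaryStatsTable,
    policy: str = "infer_by_eaf",
    eaf_window: float = DEFAULT_EAF_WINDOW,
) -> HarmonizedPairs:
    """Align every instrument with the outcome table's orientation.

    policy: ``drop_all`` drops palindromic SNPs; ``infer_by_eaf`` resolves
    them by minor-allele side when both frequencies are outside
    [0.5 − eaf_window, 0.5 + eaf_window], else drops; ``keep_as_is``
    assumes both studies report the same strand.
    """
    if policy not in PALINDROME_POLICIES:
        raise ValueError(f"unknown palindrome policy {policy!r}")
    if not (0 <= eaf_window < 0.5):
        raise ValueError(f"eaf_window must be in [0, 0.5), got {eaf_window}")

    pairs: list[HarmonizedPair] = []
    drop_log: dict[str, str] = {}
    for exp in instruments:
        out = outcome.get(exp.rsid)
        if out is None:
            drop_log[exp.rsid] = DROP_MISSING
            continue
        pair, reason = _harmonize_one(exp, out, policy, eaf_window)
        if pair is None:
            drop_log[exp.rsid] = reason  # type: ignore[assignment]
        else:
            pairs.append(pair)
    return HarmonizedPairs(
        exposure_id=instruments.trait_id,
        outcome_id=outcome.trait_id,
        pairs=tuple(pairs),
        drop_log=drop_log,
    )
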