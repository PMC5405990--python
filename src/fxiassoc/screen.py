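"""Rule-based triage of putative pathogenic mutations plus splice-score
consensus arithmetic.

Three screening rules, evaluated for every variant (an audit trail records
each rule's outcome even after an early failure):

a. rarity — every supplied reference-panel allele frequency must be below
   1% (absence from a panel counts as rare in that panel);
b. location — intronic variants more than 30 bp from the nearest exon
   boundary are rejected;
c. unannotated fallback — a variant absent from the primary reference
   panel must have sample MAF below 5%.

Splice-site impact is summarised as the percent change of each predictor's
score between the native and mutated sequence; a variant is flagged when
the magnitude exceeds 10% for at least two different algorithms. Consensus
uses unrounded deltas; one-decimal values are for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import VariantRecord, round_half_up

__all__ = [
    "ScreenCriteria",
    "SpliceScorePair",
    "RuleOutcome",
    "ScreenResult",
    "filter_candidates",
    "splice_delta",
    "splice_consensus",
    "screen_report",
]

PRIMARY_PANEL = "1000g_all"


@dataclass(frozen=True)
class ScreenCriteria:
    rare_af_threshold: float = 0.01
    intronic_distance_max_bp: int = 30
    unannotated_sample_maf_threshold: float = 0.05
    primary_panel: str = PRIMARY_PANEL

    def __post_init__(self) -> None:
        if not 0 < self.rare_af_threshold < 1:
            raise ValueError("rare_af_threshold must be in (0, 1)")
        if not 0 < self.unannotated_sample_maf_threshold < 1:
            raise ValueError("unannotated_sample_maf_threshold must be in (0, 1)")
        if self.intronic_distance_max_bp < 1:
            raise ValueError("intronic_distance_max_bp must be positive")


@dataclass(frozen=True)
class SpliceScorePair:
    algorithm: str
    native: float
    mutated: float
    scale: tuple[float, float] | None = None
    threshold_note: str | None = None

    def __post_init__(self) -> None:
        if self.scale is not None:
            lo, hi = self.scale
            for v, name in ((self.native, "native"), (self.mutated, "mutated")):
                if not lo <= v <= hi:
                    raise ValueError(
                        f"{self.algorithm}: {name} score {v} outside scale [{lo}, {hi}]"
                    )


@dataclass(frozen=True)
class RuleOutcome:
    rule: str
    passed: bool
    reason: str


@dataclass
class ScreenResult:
    variant_id: str
    rule_trail: list[RuleOutcome] = field(default_factory=list)

    @property
    def candidate(self) -> bool:
        return all(o.passed for o in self.rule_trail)


def _rule_location(v: VariantRecord, criteria: ScreenCriteria) -> RuleOutcome:
    if v.is_intronic and v.exon_distance_bp > criteria.intronic_distance_max_bp:
        return RuleOutcome(
            "location",
            False,
            f"intronic, {v.exon_distance_bp} bp from exon "
            f"(> {criteria.intronic_distance_max_bp} bp)",
        )
    if v.is_intronic:
        return RuleOutcome(
            "location", True, f"intronic, {v.exon_distance_bp} bp from exon"
        )
    return RuleOutcome("location", True, f"non-intronic ({v.feature_location})")


def _rule_rarity(v: VariantRecord, criteria: ScreenCriteria) -> RuleOutcome:
    offenders = {
        panel: af
        for panel, af in v.ref_panel_afs.items()
        if af >= criteria.rare_af_threshold
    }
    if offenders:
        return RuleOutcome(
            "rarity",
            False,
            "panel AF >= {:.2%} in {}".format(
                criteria.rare_af_threshold, ", ".join(sorted(offenders))
            ),
        )
    if v.ref_panel_afs:
        return RuleOutcome("rarity", True, "all supplied panel AFs below threshold")
    return RuleOutcome("rarity", True, "absent from every panel (treated as rare)")


def _rule_unannotated(
    v: VariantRecord, sample_maf: float | None, criteria: ScreenCriteria
) -> RuleOutcome:
    if criteria.primary_panel in v.ref_panel_afs:
        return RuleOutcome(
            "sample_maf", True, f"annotated in {criteria.primary_panel}; rule not applicable"
        )
    if sample_maf is None:
        raise ValueError(
            f"{v.variant_id}: sample MAF required for a variant absent from "
            f"{criteria.primary_panel}"
        )
    if sample_maf < criteria.unannotated_sample_maf_threshold:
        return RuleOutcome(
            "sample_maf", True, f"unannotated, sample MAF {sample_maf:.4f} < threshold"
        )
    return RuleOutcome(
        "sample_maf",
        False,
        f"unannotated, sample MAF {sample_maf:.4f} >= "
        f"{criteria.unannotated_sample_maf_threshold}",
    )


def filter_candidates(
    variants: list[VariantRecord],
    sample_mafs: dict[str, float],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[ScreenResult]:
    """Run the three-rule screen over a variant list.

    ``sample_mafs`` maps variant_id to the cohort MAF (needed for any
    variant absent from the primary panel). Every rule is evaluated for
    every variant so the trail is complete; a variant is a candidate iff
    all rules pass.
    """
    results = []
    for v in variants:
        trail = [
            _rule_location(v, criteria),
            _rule_rarity(v, criteria),
            _rule_unannotated(v, sample_mafs.get(v.variant_id), criteria),
        ]
        results.append(ScreenResult(variant_id=v.variant_id, rule_trail=trail))
    return results


def splice_delta(pair: SpliceScorePair) -> float:
    """Percent change of a splice score: 100 * (mutated - native) / native.

    The unrounded value is returned; round half-up to one decimal for
    display. Undefined for a zero native score.
    """
    if pair.native == 0:
        raise ValueError(f"{pair.algorithm}: native score is 0, percent change undefined")
    if pair.native < 0:
        raise ValueError(f"{pair.algorithm}: native score must be positive")
    return 100.0 * (pair.mutated - pair.native) / pair.native


def splice_consensus(
    pairs: list[SpliceScorePair],
    magnitude_threshold_pct: float = 10.0,
    min_algorithms: int = 2,
) -> tuple[int, bool]:
    """Count algorithms whose |percent change| exceeds the threshold and
    flag the variant when at least ``min_algorithms`` do."""
    if not pairs:
        raise ValueError("need at least one score pair")
    count = sum(
        abs(splice_delta(p)) > magnitude_threshold_pct for p in pairs
    )
    return count, count >= min_algorithms


def screen_report(results: list[ScreenResult]) -> pd.DataFrame:
    """Tidy per-variant audit trail: one row per variant, one column pair
    (pass flag, reason) per rule, plus the final candidate flag."""
    rows = []
    for r in results:
        row: dict = {"variant_id": r.variant_id}
        for o in r.rule_trail:
            row[f"{o.rule}_pass"] = o.passed
            row[f"{o.rule}_reason"] = o.reason
        row["candidate"] = r.candidate
        rows.append(row)
    return pd.DataFrame(rows)
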