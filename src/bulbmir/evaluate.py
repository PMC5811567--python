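"""Scoring a pipeline run against a synthetic study's ground truth.

Each metric follows the stage contracts: discovery recovery is judged on
the discovery pipeline's own calls, while target finding and degradome
categorisation are judged per planted miRNA/target pair (the stages under
test are given the planted mature, so their scores are not confounded by
upstream discovery misses).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import StudyResult
from .simulate import SyntheticStudy
from .targets import scan_targets


@dataclass
class RecoveryReport:
    conserved_planted: int
    conserved_recovered: int
    family_misassignments: int
    novel_eligible: int
    novel_recovered: int
    decoy_conserved_calls: int
    noise_calls: int
    targets_planted: int
    targets_found: int
    degradome_sites: int
    degradome_agreement: int

    @property
    def conserved_recovery(self) -> float:
        return self.conserved_recovered / self.conserved_planted

    @property
    def novel_recovery(self) -> float:
        return self.novel_recovered / self.novel_eligible

    @property
    def degradome_agreement_fraction(self) -> float:
        return self.degradome_agreement / self.degradome_sites


def score_against_truth(study: SyntheticStudy, result: StudyResult,
                        min_novel_reads: int = 5) -> RecoveryReport:
    manifest = study.manifest
    conserved_called = {c.mature: c for c in result.conserved_calls}
    novel_called = {c.mature for c in result.novel_calls}

    planted_cons = manifest.by_kind("conserved")
    recovered = [p for p in planted_cons if p.mature in conserved_called]
    misassigned = sum(
        1 for p in recovered if conserved_called[p.mature].family != p.family
    )

    planted_novel = manifest.by_kind("novel")
    eligible = [p for p in planted_novel
                if sum(p.realized_counts.values()) >= min_novel_reads]
    novel_recovered = sum(1 for p in eligible if p.mature in novel_called)

    decoy_calls = sum(1 for p in manifest.by_kind("decoy_conserved")
                      if p.mature in conserved_called)
    noise_calls = sum(1 for p in manifest.by_kind("noise")
                      if p.mature in conserved_called or p.mature in novel_called)

    # target finding: the scanner is handed every planted mature directly
    planted_matures = sorted({t.mirna for t in manifest.planted_targets})
    alignments = scan_targets(planted_matures, study.transcripts)
    found_keys = {(a.mirna, a.transcript_id, a.site) for a in alignments}
    targets_found = sum(
        1 for t in manifest.planted_targets
        if (t.mirna, t.transcript, tuple(t.site)) in found_keys
    )

    # degradome: category of the called site at each planted cleavage position
    from .degradome import call_cleavage_sites

    sites = call_cleavage_sites(alignments, result.degradome_profiles)
    by_position = {(s.transcript_id, s.position): s.category for s in sites}
    agreement = sum(
        1 for t in manifest.planted_targets
        if by_position.get((t.transcript, t.cleavage_position))
        == t.intended_category
    )

    return RecoveryReport(
        conserved_planted=len(planted_cons),
        conserved_recovered=len(recovered),
        family_misassignments=misassigned,
        novel_eligible=len(eligible),
        novel_recovered=novel_recovered,
        decoy_conserved_calls=decoy_calls,
        noise_calls=noise_calls,
        targets_planted=len(manifest.planted_targets),
        targets_found=targets_found,
        degradome_sites=len(manifest.planted_targets),
        degradome_agreement=agreement,
    )
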