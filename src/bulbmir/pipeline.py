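"""End-to-end discovery pipeline: glue running every stage in order.

This is the programmatic equivalent of chaining the CLI subcommands:
preprocess each tissue library, remove annotated ncRNA, call conserved then
novel miRNAs, predict targets, and validate them against the degradome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .conserved import (KnownMatureSet, MiRNACall, best_family, call_conserved,
                        locate_and_excise, match_known)
from .degradome import CleavageSite, DegradomeProfile, build_profile, \
    call_cleavage_sites
from .novel import call_novel, candidate_loci
from .preprocess import AnnotationSet, TagLibrary, TrimTally, collapse_tags, \
    filter_annotated, trim_and_filter
from .seqio import SequenceRecord
from .targets import TargetAlignment, scan_targets


@dataclass
class PipelineConfig:
    adapter: str
    min_len: int = 18
    max_len: int = 30
    max_known_mismatch: int = 2
    flank: int = 250
    novel_min_count: int = 3
    read_consistency: float = 0.75
    max_penalty: float = 4.0
    degradome_min_count: float = 1.0
    degradome_window: int = 1


@dataclass
class StudyResult:
    libraries: list[TagLibrary] = field(default_factory=list)
    trim_tallies: dict[str, TrimTally] = field(default_factory=dict)
    ncrna_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    conserved_calls: list[MiRNACall] = field(default_factory=list)
    novel_calls: list[MiRNACall] = field(default_factory=list)
    target_alignments: list[TargetAlignment] = field(default_factory=list)
    degradome_profiles: dict[str, DegradomeProfile] = field(default_factory=dict)
    degradome_unmapped: float = 0.0
    cleavage_sites: list[CleavageSite] = field(default_factory=list)

    @property
    def calls(self) -> list[MiRNACall]:
        return self.conserved_calls + self.novel_calls


def run_study(
    raw_libraries: dict[str, list[SequenceRecord]],
    transcripts: list[SequenceRecord],
    known_records: list[SequenceRecord],
    annotation: AnnotationSet,
    degradome_tags: list[SequenceRecord],
    config: PipelineConfig,
) -> StudyResult:
    """Run the whole discovery pipeline on in-memory inputs."""
    result = StudyResult()

    # 1. preprocessing: trim, filter, collapse, remove annotated ncRNA
    for name, reads in raw_libraries.items():
        trimmed, tally = trim_and_filter(reads, config.adapter,
                                         min_len=config.min_len,
                                         max_len=config.max_len)
        library = collapse_tags(trimmed, name,
                                bounds=(config.min_len, config.max_len))
        library, ncrna_tally = filter_annotated(library, annotation)
        result.libraries.append(library)
        result.trim_tallies[name] = tally
        result.ncrna_tallies[name] = ncrna_tally

    pooled: dict[str, int] = {}
    for lib in result.libraries:
        for seq, count in lib.tags.items():
            pooled[seq] = pooled.get(seq, 0) + count
    pooled_lib = TagLibrary(library_name="pooled", tags=pooled,
                            bounds=(config.min_len, config.max_len))

    # 2. conserved miRNAs
    known = KnownMatureSet.from_records(known_records)
    hits = match_known(pooled_lib, known, max_mismatch=config.max_known_mismatch)
    candidates = {
        tag: locate_and_excise(tag, transcripts, flank=config.flank)
        for tag in best_family(hits)
    }
    result.conserved_calls = call_conserved(candidates, hits, result.libraries)

    # 3. novel miRNAs from the non-conserved remainder
    conserved_matures = {c.mature for c in result.conserved_calls}
    homology_tags = {h.tag for h in hits}
    novel_pool = TagLibrary(
        library_name="novel_pool",
        tags={s: c for s, c in pooled.items()
              if s not in conserved_matures and s not in homology_tags},
        bounds=(config.min_len, config.max_len),
    )
    loci = candidate_loci(novel_pool, transcripts,
                          min_count=config.novel_min_count)
    result.novel_calls = call_novel(
        loci, transcripts, result.libraries,
        read_consistency=config.read_consistency, flank=config.flank)

    # conserved/novel disjointness is a pipeline invariant
    for call in result.novel_calls:
        assert all(h.tag != call.mature for h in hits), \
            "novel call overlaps the known set within the mismatch budget"

    # 4. targets and degradome validation
    result.target_alignments = scan_targets(
        result.calls, transcripts, max_penalty=config.max_penalty)
    degradome_lib = collapse_tags(degradome_tags, "degradome",
                                  bounds=(1, 10**6))
    result.degradome_profiles, result.degradome_unmapped = build_profile(
        degradome_lib, transcripts)
    result.cleavage_sites = call_cleavage_sites(
        result.target_alignments, result.degradome_profiles,
        min_count=config.degradome_min_count,
        window=config.degradome_window)
    return result
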