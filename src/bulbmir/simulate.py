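"""Ground-truthed synthetic data: transcripts with planted hairpin
precursors, tissue-specific small-RNA libraries, ncRNA contaminants and
degradome tags with controlled cleavage-site abundance classes.

Every planted feature is recorded in a :class:`GroundTruthManifest` so each
pipeline stage can be scored against known truth. Generation is fully
deterministic given the seed: the same seed reproduces byte-identical
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .degradome import DegradomeProfile, categorize_site
from .fold import HairpinFold, PrecursorCandidate, amfe_mfei, fold_mfe, star_of, \
    validate_stemloop
from .preprocess import AnnotationSet, NCRNA_CLASSES
from .seqio import SequenceRecord, reverse_complement

#: canonical 3' sequencing adapter (RNA form) appended to simulated reads
DEFAULT_ADAPTER = "UCGUAUGCCGUCUUCUGCUUGU"

DEFAULT_TISSUES = ("flower", "leaf", "bulblet", "bulb")

_ALPHABET = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def synthetic_ncrna_set(n_per_class: int = 3, seed: int = 20180213) -> AnnotationSet:
    """A miniature labelled ncRNA reference (synthetic stand-in, not Rfam).

    Deterministic: the records depend only on the arguments, never on the
    caller's rng, so contaminant reads and the filter reference agree.
    """
    rng = np.random.default_rng(seed)
    records = []
    for cls in NCRNA_CLASSES:
        for k in range(n_per_class):
            length = int(rng.integers(90, 220))
            rec = SequenceRecord(
                id=f"synth_{cls}_{k + 1}|{cls}",
                residues=_random_seq(rng, length),
            )
            records.append((rec, cls))
    return AnnotationSet(records)


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    kind: str  # conserved | novel | decoy_conserved | noise
    family: Optional[str]
    transcript: str
    offset: int  # mature start, transcript coordinates
    star: Optional[tuple[int, int]]  # transcript coordinates
    mean_counts: dict[str, float] = field(default_factory=dict)
    realized_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PlantedContaminant:
    sequence: str
    ncrna_class: str
    counts: dict[str, int]


@dataclass
class PlantedTarget:
    mirna_name: str
    mirna: str
    transcript: str
    site: tuple[int, int]  # half-open, transcript coordinates
    cleavage_position: int  # nucleotide paired to miRNA position 10
    intended_category: int
    site_count: float


@dataclass
class GroundTruthManifest:
    seed: int
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    planted_contaminants: list[PlantedContaminant] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[PlantedMiRNA]:
        return [p for p in self.planted_mirnas if p.kind == kind]


def make_hairpin(
    mature: str,
    loop_len: int,
    star_mismatches: int,
    rng: np.random.Generator,
    max_tries: int = 25,
) -> tuple[str, dict]:
    """Build a precursor: mature arm + loop + near-reverse-complement star.

    The star carries `star_mismatches` pair-breaking substitutions and the
    canonical 2-nt 3' overhang. For star_mismatches <= 3 the construct is
    re-folded and must pass stem-loop validation (resampling the loop and
    overhang a bounded number of times); above 3 it is flagged as
    negative-control material that may not validate.
    """
    L = len(mature)
    if not 20 <= L <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 4:
        raise ValueError("loop_len must be >= 4 (folder minimum plus margin)")

    pair_break = {"A": "C", "C": "A", "G": "A", "U": "C"}
    paired_arm = reverse_complement(mature[:L - 2])
    may_not_validate = star_mismatches > 3

    last = None
    for _ in range(max_tries):
        star = list(paired_arm)
        if star_mismatches:
            positions = rng.choice(len(star), size=min(star_mismatches, len(star)),
                                   replace=False)
            for p in positions:
                star[p] = pair_break[star[p]]
        star_seq = "".join(star) + _random_seq(rng, 2)  # 2-nt 3' overhang
        loop = _random_seq(rng, loop_len)
        precursor = mature + loop + star_seq
        geometry = {
            "mature": (0, L),
            "star": (L + loop_len, len(precursor)),
            "may_not_validate": may_not_validate,
        }
        if may_not_validate:
            return precursor, geometry
        fold = fold_mfe(precursor)
        amfe, mfei, gc = amfe_mfei(fold)
        cand = PrecursorCandidate(
            source_id="hairpin", window=(0, len(precursor)), fold=fold,
            mature=(0, L), star=star_of(fold, (0, L)),
            amfe=amfe, mfei=mfei, gc_percent=gc,
        )
        ok, reasons = validate_stemloop(cand)
        if ok:
            return precursor, geometry
        last = reasons
    raise RuntimeError(f"could not build a validating hairpin: {last}")


def make_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    planted_hairpins: list[tuple[str, str, dict]],
    planted_sites: list[tuple[str, str]],
    rng: np.random.Generator,
    manifest: Optional[GroundTruthManifest] = None,
) -> tuple[list[SequenceRecord], GroundTruthManifest]:
    """Uniform-random transcripts with planted precursors and target sites.

    planted_hairpins: (name, precursor sequence, geometry from make_hairpin);
    planted_sites: (name, site sequence). Each planted feature goes into its
    own transcript (plants beyond n_transcripts raise). Background is
    rejection-sampled so no planted mature recurs verbatim elsewhere.
    """
    n_planted = len(planted_hairpins) + len(planted_sites)
    if n_planted > n_transcripts:
        raise ValueError("more planted features than transcripts")
    if manifest is None:
        manifest = GroundTruthManifest(seed=-1)

    lo, hi = length_range
    transcripts: list[SequenceRecord] = []
    matures = [h[2].get("mature_sequence", h[1][h[2]["mature"][0]:h[2]["mature"][1]])
               for h in planted_hairpins]

    def background(length: int) -> str:
        for _ in range(50):
            seq = _random_seq(rng, length)
            if not any(m in seq for m in matures):
                return seq
        raise RuntimeError("could not sample clean background")

    plant_items: list[tuple[str, str, Optional[dict]]] = [
        (name, seq, geom) for name, seq, geom in planted_hairpins
    ] + [(name, seq, None) for name, seq in planted_sites]

    for idx in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        tid = f"synthT{idx + 1:04d}"
        if idx < len(plant_items):
            name, insert, geom = plant_items[idx]
            length = max(length, len(insert) + 40)
            offset = int(rng.integers(10, length - len(insert) - 10))
            seq = background(offset) + insert + background(length - offset - len(insert))
            transcripts.append(SequenceRecord(id=tid, residues=seq))
            if geom is not None:
                m0, m1 = geom["mature"]
                s0, s1 = geom["star"]
                geom["transcript"] = tid
                geom["mature_transcript"] = (offset + m0, offset + m1)
                geom["star_transcript"] = (offset + s0, offset + s1)
            else:
                for t in manifest.planted_targets:
                    if t.mirna_name == name and t.transcript == "":
                        t.transcript = tid
                        t.site = (offset, offset + len(insert))
        else:
            transcripts.append(SequenceRecord(id=tid, residues=background(length)))

    # verify: every planted mature occurs exactly where planted, nowhere else
    for (name, _, geom), mature in zip(planted_hairpins, matures):
        hits = sum(rec.residues.count(mature) for rec in transcripts)
        if hits != 1:
            raise RuntimeError(f"planted mature {name} occurs {hits} times")
    return transcripts, manifest


def _lognormal_count(rng: np.random.Generator, mean: float) -> int:
    """Integer count log-normally scattered around a mean (sigma 0.4)."""
    if mean <= 0:
        return 0
    return int(round(float(rng.lognormal(np.log(mean), 0.4))))


def simulate_srna_libraries(
    manifest: GroundTruthManifest,
    tissues: tuple[str, ...],
    adapter: str,
    rng: np.random.Generator,
    jitter_rate: float = 0.1,
    star_fraction: float = 0.2,
    contaminant_reads: int = 60,
    noise_reads: int = 40,
    no_adapter_reads: int = 10,
    annotation: Optional[AnnotationSet] = None,
    transcripts: Optional[list[SequenceRecord]] = None,
) -> dict[str, list[SequenceRecord]]:
    """Per-tissue raw small-RNA reads (adapter appended).

    For each planted miRNA the per-tissue read count is drawn log-normally
    around its manifest mean; a star_fraction share of star reads is added
    when the plant has a star. Contaminant ncRNA fragments, random noise
    reads and a few adapterless reads complete the library. The manifest's
    realized_counts are updated with the exact-sequence mature counts.
    """
    if annotation is None:
        annotation = synthetic_ncrna_set()
    by_id = {r.id: r for r in (transcripts or [])}
    libraries: dict[str, list[SequenceRecord]] = {}
    for tissue in tissues:
        reads: list[SequenceRecord] = []
        serial = 0

        def emit(seq: str) -> None:
            nonlocal serial
            serial += 1
            reads.append(SequenceRecord(id=f"{tissue}_r{serial}",
                                        residues=seq + adapter))

        for plant in manifest.planted_mirnas:
            mean = plant.mean_counts.get(tissue, 0.0)
            count = _lognormal_count(rng, mean)
            exact = 0
            if plant.kind == "noise" and plant.transcript in by_id:
                # degradation-like noise: 5' ends scattered over ~90 nt so
                # the locus never shows a Dicer-consistent read stack
                ref = by_id[plant.transcript].residues
                for _ in range(count):
                    off = plant.offset + int(rng.integers(-45, 46))
                    length = int(rng.integers(20, 23))
                    off = min(max(off, 0), len(ref) - length)
                    frag = ref[off:off + length]
                    if frag == plant.mature:
                        exact += 1
                    emit(frag)
                plant.realized_counts[tissue] = exact
                continue
            for _ in range(count):
                seq = plant.mature
                if jitter_rate and rng.random() < jitter_rate:
                    seq = seq[1:] if rng.random() < 0.5 else seq[:-1]
                else:
                    exact += 1
                emit(seq)
            plant.realized_counts[tissue] = exact
            if plant.star is not None and plant.transcript in by_id:
                s0, s1 = plant.star
                star_seq = by_id[plant.transcript].residues[s0:s1]
                star_count = _lognormal_count(rng, mean * star_fraction)
                for _ in range(star_count):
                    emit(star_seq)
                plant.star_counts[tissue] = star_count

        contaminant_pool = [rec.residues for rec, _ in annotation.records]
        for _ in range(contaminant_reads):
            k = int(rng.integers(len(contaminant_pool)))
            ref = contaminant_pool[k]
            frag_len = int(rng.integers(20, 25))
            start = int(rng.integers(0, len(ref) - frag_len))
            emit(ref[start:start + frag_len])

        for _ in range(noise_reads):
            emit(_random_seq(rng, int(rng.integers(16, 33))))
        for _ in range(no_adapter_reads):
            serial += 1
            reads.append(SequenceRecord(
                id=f"{tissue}_r{serial}",
                residues=_random_seq(rng, int(rng.integers(30, 50)))))
        libraries[tissue] = reads
    return libraries


#: per-category degradome scenarios: (site count, background counts)
_CATEGORY_SCENARIOS = {
    0: (8.0, [3.0, 2.0, 2.0]),
    1: (8.0, [8.0, 2.0, 1.0]),
    2: (5.0, [12.0, 2.0, 2.0, 1.0]),
    3: (2.0, [9.0, 7.0, 3.0]),
    4: (1.0, [6.0, 3.0]),
}


def simulate_degradome(
    manifest: GroundTruthManifest,
    transcripts: list[SequenceRecord],
    rng: np.random.Generator,
    tag_len: int = 20,
) -> list[SequenceRecord]:
    """Degradome tags realising each planted target's intended category.

    Site tags start exactly at the nucleotide paired to miRNA position 10;
    background tags are placed well away from the site with counts arranged
    so categorize_site must return the intended category (self-verified on
    the constructed profile before emission).
    """
    by_id = {r.id: r for r in transcripts}
    reads: list[SequenceRecord] = []
    serial = 0

    def emit(seq: str, count: int) -> None:
        nonlocal serial
        for _ in range(count):
            serial += 1
            reads.append(SequenceRecord(id=f"pare_r{serial}", residues=seq))

    all_seq = [r.residues for r in transcripts]

    def unique_tag(tid: str, pos: int) -> Optional[str]:
        seq = by_id[tid].residues[pos:pos + tag_len]
        if len(seq) < tag_len:
            return None
        if sum(s.count(seq) for s in all_seq) != 1:
            return None
        return seq

    for target in manifest.planted_targets:
        s0, s1 = target.site
        cleave = s1 - 10
        target.cleavage_position = cleave
        site_count, backgrounds = _CATEGORY_SCENARIOS[target.intended_category]
        target.site_count = site_count

        tag = unique_tag(target.transcript, cleave)
        if tag is None:
            raise RuntimeError(f"cannot place site tag for {target.mirna_name}")
        profile_counts = {cleave: site_count}
        emit(tag, int(site_count))

        length = len(by_id[target.transcript].residues)
        for bg_count in backgrounds:
            for _ in range(60):
                pos = int(rng.integers(0, length - tag_len))
                if abs(pos - cleave) <= 3 or pos in profile_counts:
                    continue
                bg_tag = unique_tag(target.transcript, pos)
                if bg_tag is not None:
                    profile_counts[pos] = bg_count
                    emit(bg_tag, int(bg_count))
                    break
            else:
                raise RuntimeError("could not place background degradome tag")

        profile = DegradomeProfile(transcript_id=target.transcript,
                                   counts=profile_counts)
        got = categorize_site(profile, cleave)
        if got != target.intended_category:
            raise AssertionError(
                f"scenario for category {target.intended_category} yields {got}"
            )
    return reads


@dataclass
class SyntheticStudy:
    """A complete synthetic experiment plus its ground truth."""

    manifest: GroundTruthManifest
    transcripts: list[SequenceRecord]
    known_records: list[SequenceRecord]
    annotation: AnnotationSet
    libraries: dict[str, list[SequenceRecord]]  # raw reads, adapter appended
    degradome_tags: list[SequenceRecord]
    adapter: str
    tissues: tuple[str, ...]


_SPECIES = ("osa", "ath", "zma", "tae", "hvu")


def simulate_study(
    seed: int,
    n_conserved: int = 20,
    n_novel: int = 15,
    n_decoy_conserved: int = 4,
    n_noise_loci: int = 4,
    n_targets_per_category: int = 2,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    adapter: str = DEFAULT_ADAPTER,
    transcript_length: tuple[int, int] = (320, 480),
    jitter_rate: float = 0.1,
) -> SyntheticStudy:
    """Generate a full ground-truthed study with the default conditions.

    Known mature miRNAs are synthesised with miRBase-style names; planted
    conserved matures sit 0-2 mismatches from a known entry, decoys at 3,
    and novel matures far from every known entry. Targets cycle through the
    five degradome categories.
    """
    rng = np.random.default_rng(seed)
    manifest = GroundTruthManifest(seed=seed)

    # --- known mature set and planted mature sequences -------------------
    known_records: list[SequenceRecord] = []
    known_seqs: list[str] = []
    for i in range(n_conserved + n_decoy_conserved):
        species = _SPECIES[i % len(_SPECIES)]
        seq = "U" + _random_seq(rng, 20)
        known_records.append(SequenceRecord(id=f"{species}-miR{150 + i}",
                                            residues=seq))
        known_seqs.append(seq)

    pair_break = {"A": "C", "C": "A", "G": "A", "U": "C"}

    def mutate(seq: str, k: int) -> str:
        out = list(seq)
        for p in rng.choice(len(seq), size=k, replace=False):
            out[p] = pair_break[out[p]]
        return "".join(out)

    hairpins: list[tuple[str, str, dict]] = []
    for i in range(n_conserved):
        d = i % 3  # 0, 1 or 2 mismatches from the known entry
        mature = mutate(known_seqs[i], d)
        name = f"cons{i + 1:02d}"
        precursor, geom = make_hairpin(mature, loop_len=int(rng.integers(8, 14)),
                                       star_mismatches=int(rng.integers(0, 3)),
                                       rng=rng)
        geom["mature_sequence"] = mature
        hairpins.append((name, precursor, geom))
        manifest.planted_mirnas.append(PlantedMiRNA(
            name=name, mature=mature, kind="conserved",
            family=f"MIR{150 + i}", transcript="", offset=-1, star=None))

    for i in range(n_decoy_conserved):
        mature = mutate(known_seqs[n_conserved + i], 3)
        name = f"decoy{i + 1:02d}"
        precursor, geom = make_hairpin(mature, loop_len=int(rng.integers(8, 14)),
                                       star_mismatches=1, rng=rng)
        geom["mature_sequence"] = mature
        hairpins.append((name, precursor, geom))
        manifest.planted_mirnas.append(PlantedMiRNA(
            name=name, mature=mature, kind="decoy_conserved",
            family=None, transcript="", offset=-1, star=None))

    novel_lengths = [20, 21, 21, 21, 22, 23, 24]
    for i in range(n_novel):
        L = novel_lengths[i % len(novel_lengths)]
        mature = "U" + _random_seq(rng, L - 1)
        name = f"novel{i + 1:02d}"
        precursor, geom = make_hairpin(mature, loop_len=int(rng.integers(8, 14)),
                                       star_mismatches=int(rng.integers(0, 3)),
                                       rng=rng)
        geom["mature_sequence"] = mature
        hairpins.append((name, precursor, geom))
        manifest.planted_mirnas.append(PlantedMiRNA(
            name=name, mature=mature, kind="novel",
            family=None, transcript="", offset=-1, star=None))

    for i in range(n_noise_loci):
        mature = _random_seq(rng, 21)
        manifest.planted_mirnas.append(PlantedMiRNA(
            name=f"noise{i + 1:02d}", mature=mature, kind="noise",
            family=None, transcript="", offset=-1, star=None))

    # --- target sites ----------------------------------------------------
    conserved_pool = [p for p in manifest.planted_mirnas if p.kind == "conserved"]
    novel_pool = [p for p in manifest.planted_mirnas if p.kind == "novel"]
    target_donors = [p for pair in zip(conserved_pool, novel_pool) for p in pair]
    target_donors += conserved_pool[len(novel_pool):] + novel_pool[len(conserved_pool):]
    sites: list[tuple[str, str]] = []
    cat_cycle = [0, 1, 2, 3, 4] * n_targets_per_category
    for cat, donor in zip(cat_cycle, target_donors):
        site_seq = reverse_complement(donor.mature)
        sites.append((donor.name, site_seq))
        manifest.planted_targets.append(PlantedTarget(
            mirna_name=donor.name, mirna=donor.mature, transcript="",
            site=(-1, -1), cleavage_position=-1,
            intended_category=cat, site_count=0.0))

    # --- transcripts: one per hairpin/site plus noise-tag hosts ----------
    noise_plants = [(p.name, p.mature) for p in manifest.planted_mirnas
                    if p.kind == "noise"]
    n_background = 5
    n_transcripts = len(hairpins) + len(sites) + len(noise_plants) + n_background
    transcripts, manifest = make_transcriptome(
        n_transcripts, transcript_length, hairpins,
        sites + noise_plants, rng, manifest=manifest)

    hairpin_geoms = {name: geom for name, _, geom in hairpins}
    noise_names = {name for name, _ in noise_plants}
    for plant in manifest.planted_mirnas:
        geom = hairpin_geoms.get(plant.name)
        if geom is not None:
            plant.transcript = geom["transcript"]
            plant.offset = geom["mature_transcript"][0]
            plant.star = geom["star_transcript"]
        elif plant.name in noise_names:
            for rec in transcripts:
                pos = rec.residues.find(plant.mature)
                if pos != -1:
                    plant.transcript, plant.offset = rec.id, pos
                    break

    # --- abundances -------------------------------------------------------
    for plant in manifest.planted_mirnas:
        if plant.kind == "noise":
            base = 12.0
        else:
            base = float(rng.lognormal(np.log(25.0), 0.6))
        for tissue in tissues:
            plant.mean_counts[tissue] = base * float(rng.lognormal(0.0, 0.5))

    annotation = synthetic_ncrna_set()
    libraries = simulate_srna_libraries(
        manifest, tissues, adapter, rng, jitter_rate=jitter_rate,
        annotation=annotation, transcripts=transcripts)
    degradome_tags = simulate_degradome(manifest, transcripts, rng)

    return SyntheticStudy(
        manifest=manifest, transcripts=transcripts,
        known_records=known_records, annotation=annotation,
        libraries=libraries, degradome_tags=degradome_tags,
        adapter=adapter, tissues=tissues,
    )
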