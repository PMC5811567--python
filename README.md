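# bulbmir

Discovery and validation of plant microRNAs from small-RNA sequencing, built
around the tissue panel of the bulb-forming lily *Lilium lancifolium*
(flower, leaf, bulblet, bulb). The package covers the full desk-side
analysis chain:

1. **Preprocessing** — 3' adapter trimming, 18–30 nt length filtering,
   collapsing reads to unique tags with counts, and removal of
   rRNA/tRNA/snRNA/snoRNA contaminants.
2. **Conserved miRNA identification** — homology to known mature miRNAs
   within a 2-mismatch budget, anchoring on transcripts, folding of flanking
   windows and stem-loop validation.
3. **Novel miRNA calling** — rule-based discovery from unannotated tag loci:
   a Dicer-consistent read stack on a validated hairpin.
4. **Precursor statistics** — minimum free energy (MFE) from an internal,
   exactly reproducible folding model; adjusted MFE
   `AMFE = (MFE/length) × 100`; minimal folding energy index
   `MFEI = AMFE / (G+C)%`.
5. **Target prediction** — position-weighted complementarity penalties
   (match 0, G:U 0.5, mismatch 1.0, gap 2.0; positions 2–13 doubled) with a
   seed over miRNA positions 2–8 and a default cutoff of 4.0.
6. **Degradome (PARE) validation** — transcript 5'-end profiles, cleavage
   sites opposite miRNA positions 10–11, and the 5-category classification
   (0 unique maximum, 1 tied maximum, 2 above median, 3 at or below median,
   4 single read).
7. **Expression** — stem-loop qPCR quantification by 2^−ΔΔCT and
   miRNA/target anti-correlation across tissues (Spearman).
8. **Synthetic data** — a ground-truthed generator (transcripts with planted
   hairpins, tissue read stacks, ncRNA contaminants, degradome tags with
   controlled category scenarios) so every stage is testable end to end
   without downloads.

A bundled catalog of the published *L. lancifolium* mature miRNAs
(25 conserved across 17 families; 44 novel) supports the composition
statistics without any external databases.

## Worked example

```python
from bulbmir.simulate import simulate_study
from bulbmir.pipeline import PipelineConfig, run_study
from bulbmir.evaluate import score_against_truth

study = simulate_study(seed=1)                     # 20 conserved + 15 novel planted
result = run_study(study.libraries, study.transcripts, study.known_records,
                   study.annotation, study.degradome_tags,
                   PipelineConfig(adapter=study.adapter))
report = score_against_truth(study, result)
print(f"conserved recovery {report.conserved_recovery:.0%}, "
      f"novel recovery {report.novel_recovery:.0%}, "
      f"category agreement {report.degradome_agreement_fraction:.0%}")
```

prints

```
conserved recovery 100%, novel recovery 87%, category agreement 100%
```

meaning: all 20 planted conserved miRNAs were re-identified with the correct
family, 13 of the 15 well-expressed planted novel hairpins were called, and
every degradome-supported cleavage site was classified into exactly the
abundance category the generator intended.

The same stages are available from the shell:

```sh
bulbmir simulate --seed 7 --out sim/
bulbmir preprocess --reads sim/flower.fastq --adapter UCGUAUGCCGUCUUCUGCUUGU \
    --annotation sim/ncrna.fasta --out sim/flower
bulbmir conserved --tags sim/flower.tags.fasta --known sim/known_mature.fasta \
    --transcripts sim/transcripts.fasta --out sim/conserved.tsv
```

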