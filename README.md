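# tedyn

Structural annotation and evolutionary dynamics of the two transposable
element classes that dominate plant genomes: **MITEs** (miniature
inverted-repeat transposable elements) and **LTR retrotransposons**.  The
package re-implements, as a tested and reusable pipeline, a comparative
multi-genome analysis of these elements — detection, family classification,
amplification dating, insertion polymorphism, genomic context, small-RNA
profiling and insertion/elimination dynamics — together with a
synthetic-genome module that plants every kind of ground truth the analysis
assumes, so the whole pipeline is testable without any genome download.

It is written for sequence-analysis researchers who want transparent,
rule-based replacements for the usual tool chain (MITE-Hunter +
RepeatMasker + UCLUST; LTR_FINDER + BLAST) with every threshold explicit
and every stage validated against planted truth.

## The model in brief

**MITE** — a non-autonomous DNA transposon under 800 bp with a terminal
inverted repeat (TIR, 10–30 bp, ≤ 1 mismatch between termini) and an exact
target-site duplication (TSD) whose length is diagnostic of the
superfamily: TTA/TAA → *PIF-Harbinger*, 8 bp → *hAT*, 9–10 bp → *Mutator*.
Families are greedy centroid clusters at 80% global-alignment identity; a
genomic copy is *full-length* when its homology hit covers > 90% of the
family representative.

**Dating** — for a family of full-length copies, the observed pairwise
proportion of differing sites *p* is corrected with Jukes–Cantor,

```
k = -(3/4) ln(1 - 4p/3)
```

and converted to years with the molecular clock **T = k / 2r**, where
r = 5.62 × 10⁻⁹ substitutions/site/year (twice a coding-region rate of
2.81 × 10⁻⁹).  A unimodal pairwise-divergence histogram with a star-shaped
neighbor-joining tree indicates a single amplification burst.

**P/A polymorphism** — a MITE locus is compared between two genomes by
mapping its 1 kb flanks onto the partner: the locus is *allelic* when both
flanks anchor uniquely to the same chromosome and strand, reciprocally,
with inner ends < 1 kb apart; the insertion is *present in both* when a
copy of the same family lies between the anchors.  The polymorphic ratio is
`100 · (absent_in_reference + absent_in_partner) / common_loci`.

**LTR retrotransposon** — two direct long terminal repeats (each TG…CA)
around an internal region with a primer binding site (PBS) and polypurine
tract (PPT), flanked by an exact 4–6 bp TSD.  The two LTRs are identical at
insertion, so their divergence dates the element (same clock as above).
The genome-wide age histogram decays as **y = a · 2^(b·x)** (x in My), whose
half-life is −1/b; *solo-LTRs* (a single LTR with TSD flanks, the footprint
of unequal recombination) are counted per family and the S/C ratio
(solo/complete) is correlated with candidate drivers by Spearman rank
correlation.

## Worked example

```python
from tedyn import synthio, mite, pa, ltrdyn
from tedyn.evodate import DatingConfig, date_from_k, jc_correct, p_distance
from tedyn.seqio import FeatureInterval

# 1. dating a family whose mean pairwise divergence is 0.26
t = date_from_k(0.26, DatingConfig()) / 1e6
print(f"amplification time: {t:.1f} My")

# 2. P/A polymorphism on a synthetic pair with 40% planted polymorphism
cfg = synthio.SynthConfig(
    seed=7, genome_length=400_000, n_chromosomes=2,
    mite_families=[
        synthio.MiteFamilyPlan("Mutator", 14, 9, 260, 40, (0.05,)),
        synthio.MiteFamilyPlan("hAT", 12, 8, 400, 20, (0.02,)),
    ],
    ltr_families=[], gene_density=20, pa_polymorphism_rate=0.4,
)
rec_a, rec_b, _fa, _fb, truth = synthio.generate_pair(cfg)
seeds = [mite.MiteElement(location=FeatureInterval(f, 0, len(s), ".", "repeat_region"),
                          sequence=s) for f, s in truth.family_seeds.items()]
families = mite.cluster_families(seeds)
copies_a = [c for c in mite.annotate_copies(rec_a, families) if c.full_length]
copies_b = [c for c in mite.annotate_copies(rec_b, families) if c.full_length]
_loci, summary = pa.compare_pair(copies_a, rec_a, copies_b, rec_b, "partner")
print(f"common loci: {summary.common_loci}, polymorphic ratio: {summary.polymorphic_ratio:.2f}%")

# 3. LTR half-life from 2000 simulated elements planted at 1.8 My
pairs = synthio.simulate_ltr_pairs(2000, half_life_my=1.8, ltr_length=1500, seed=1)
times = [jc_correct(p_distance(a, b)) / (2 * DatingConfig().rate) for _t, a, b in pairs]
fit = ltrdyn.fit_age_distribution(times)
print(f"fitted decay: a={fit.a:.0f}, b={fit.b:.3f}, half-life={fit.half_life:.2f} My")
```

prints

```
amplification time: 23.1 My
common loci: 60, polymorphic ratio: 40.00%
fitted decay: a=402, b=-0.583, half-life=1.72 My
```

A divergence of 0.26 dates an amplification burst to ~23 My; the P/A caller
recovers the planted 40% polymorphic ratio exactly on a clean pair; and the
decay fit recovers a planted 1.8 My half-life within the sampling error of
one 2000-element dataset.

## Command line

Every stage is also exposed as a `tedyn` subcommand over FASTA/GFF3/TSV
files: `synth`, `mite-annotate`, `mite-date`, `pa-call`, `context`, `srna`,
`ltr-detect`, `ltr-date`.  For example:

```bash
tedyn synth --config config.yaml --outdir out --pair
tedyn pa-call --ref-genome out/genomeA.fa --partner-genome out/genomeB.fa \
              --seeds out/seeds.fa --out pa
```

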