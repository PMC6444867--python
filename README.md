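# plasmacna

Genome-wide copy-number instability scoring of plasma cell-free DNA (cfDNA)
from shallow whole-genome sequencing, droplet-digital-PCR copy-number
calling, and the downstream survival biomarker statistics — as a tested,
reusable Python library with a thin command-line front end.

## Who this is for

Liquid-biopsy groups quantifying tumor burden from low-depth (sub-1x)
plasma WGS. Tumor-derived cfDNA carries the tumor's copy-number
alterations (CNAs); the dosage imbalance they create in read depth is
detectable at very low coverage if the genome is aggregated into large
bins. The package turns aligned reads into a single per-sample genomic
instability score, calls a specific amplification (VEGFA, against the
diploid reference gene EIF2C1) from ddPCR droplet counts, and relates
both biomarkers to response and survival endpoints.

## The model

The autosomes are tiled into 1 Mb bins (2897 bins for hg19; a BED
blacklist removes poorly mappable centromere/telomere bins). Reads are
retained if primary, non-duplicate and MAPQ ≥ 60, and counted by leftmost
base. Counts are GC-corrected by LOESS of count on bin GC fraction
(multiplicative: raw × median(fitted)/fitted), then expressed as
percentages of the usable-bin total. A panel of healthy controls gives
each bin a mean m_j and standard deviation s_j of these percentages, and a
test sample's bin percentage x_j becomes

    Z_j = (x_j − m_j) / s_j

Whole-genome instability is summarized as

    I = Σ_j |Z_j| over usable bins with |Z_j| > 2      (I-score)
    S = Σ_j Z_j²  over all usable bins                 (S-score)

A sample distributed like the panel has Z ≈ 0 everywhere and I-score near
zero; gains (Z > 2) and losses (Z < −2) accumulate into I as tumor
fraction rises.

For ddPCR, template molecules partition over ~20,000 droplets
approximately Poisson, so a channel with k positive of n accepted droplets
has λ = −ln(1 − k/n) copies per droplet, and the VEGFA copy number per
diploid genome is 2·λ_VEGFA/λ_EIF2C1, called amplified above the
healthy-control mean + 3 SD.

The survival layer implements median dichotomization (ties to the low
group), quartile grouping, disease control rate (CR/PR/SD/non-CR-non-PD)
with a Wald 95% CI, the elevated-versus-healthy rule (strictly above the
controls' 90th percentile), Kaplan-Meier estimation, the log-rank test,
and univariable/multivariable Cox proportional-hazards fits with
univariable screening at α = 0.05.

A synthetic-data module generates every input with known ground truth:
negative-binomial bin counts with a smooth GC bias and arm-level CNAs
(+1q, +8q, −1p, −4q, −8p) diluted by tumor fraction, SAM fixtures, duplex
droplet counts, and proportional-hazards survival times.

## Worked example

`python examples/instability_pipeline.py` simulates 14 healthy controls
and 4 patients on a 200-bin toy genome, builds the panel, and scores each
patient:

```
panel: 14 controls, 200/200 scorable bins
patient_01  tumor fraction 0.00  I-score    53.3  S-score    295.7  gains  11  losses  10
patient_02  tumor fraction 0.10  I-score    57.4  S-score    292.3  gains  11  losses  10
patient_03  tumor fraction 0.20  I-score    69.4  S-score    358.2  gains  12  losses  15
patient_04  tumor fraction 0.30  I-score    99.6  S-score    446.5  gains  21  losses  14
exact-mean sample I-score: 0.0
```

The I-score climbs with tumor fraction; a sample equal to the panel means
scores exactly zero, while real tumor-free samples keep a small positive
sampling baseline from chance |Z| > 2 excursions (here ≈ 53 on 200 bins).
Other examples: `count_from_sam.py` (SAM counting with MAPQ/duplicate
filters), `vegfa_ddpcr.py` (droplet counts → copy number → amplification
call), `survival_biomarkers.py` (median split, DCR, KM, log-rank, Cox).

The same stages are available as a CLI for file-based runs:

```
plasmacna simulate --seed 5 --outdir run/
plasmacna gc-correct --counts run/patient_01.raw.tsv --bins run/bins.tsv --gc run/gc.tsv --out run/patient_01.pct.tsv
plasmacna panel --controls run/control_01.pct.tsv ... --bins run/bins.tsv --out-prefix run/panel
plasmacna score --sample run/patient_01.pct.tsv --panel run/panel --bins run/bins.tsv --out-prefix run/patient_01
```

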