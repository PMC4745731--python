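# pascore

Pathway-activation scoring and drug-score prediction from case/control gene
expression.

Targeted anticancer drugs inhibit one or a few proteins, yet response in
individual patients is hard to predict from the target list alone. `pascore`
implements a transcriptome-only approach: it detects which intracellular
signalling pathways a tumour sample has activated relative to normal tissue
and then ranks targeted drugs by their ability to counteract that
tumour-specific activation. It is aimed at computational biologists working
with bulk (or pseudo-bulk) expression cohorts who want per-sample pathway
activation values, per-sample drug scores, responder calls, and the
cohort-level statistics that relate predicted responder fractions to observed
clinical response rates.

## Model

For each gene *n* and case sample, the **case-to-normal ratio** is

    CNR_n = (expression of n in the case sample) / (mean expression of n across controls)

A gene enters pathway scoring only if its **beyond-tolerance-interval flag**
is set: BTIF_n = 1 when the case value is statistically distinguishable from
the control distribution (two-sided prediction-interval t-test on log2
values, p < α, default α = 0.05) **and** the CNR lies outside the
fold-change interval (0.66, 1.5).

**Pathway activation strength** of pathway *p* in a sample is the signed,
gated sum over its member proteins:

    PAS_p = Σ_n NII_np · ARR_np · BTIF_n · lg(CNR_n)

where NII_np ∈ {0,1} is pathway membership, ARR_np ∈ {−1,+1} the
activator/repressor role of protein *n* in pathway *p*, and lg is log10.
PAS > 0 means the pathway is activated in the sample, PAS < 0 inhibited.

The **drug score** of drug *d* sums activation over every
(target, pathway) incidence of the drug's targets:

    DS_d = Σ_t DTI_dt Σ_p NII_tp · AMCF_p · PAS_p

where DTI_dt ∈ {0,1} marks the drug's targets and AMCF_p ∈ {−1,+1} records
whether activating the pathway promotes or inhibits mitosis. A pathway is
counted once per target of the drug it contains. High DS marks a drug whose
targets sit in tumour-promoting pathways the sample has activated.

For antibody–cytotoxin conjugates (killer Mabs) a reduced variant drops the
role and mitosis weights (ARR = AMCF = 1): any overexpressed target attracts
the toxin regardless of its signalling role.

Predicted **responders** are samples with DS above a cutoff (default 250,
suited to genome-scale pathway collections) or with strictly positive DS.
Two validation statistics operate on responder calls: Pearson correlation of
predicted responder fractions against clinical-trial response rates, and
Fisher's exact comparison of responder proportions between two cohorts.

## Worked example

Simulate a small cohort with one activated pathway (`pw01`, fold 6, five
member genes) plus a drug panel whose `ON_*` drugs target the activated
pathway and whose `OFF_*` drugs target quiescent ones, then score it:

```
pascore simulate --spec demo_spec.yaml --outdir demo
pascore pas   --expr demo/expression.tsv --phenotype demo/phenotype.tsv \
              --pathways demo/pathways.tsv -o demo/pas.tsv
pascore score --pas demo/pas.tsv --pathways demo/pathways.tsv \
              --drug-targets demo/drug_targets.tsv -o demo/ds.tsv
pascore rank  --ds demo/ds.tsv
```

with `demo_spec.yaml`:

```yaml
n_genes: 60
n_pathways: 3
genes_per_pathway: 5
n_cases: 6
n_controls: 5
activated_pathways: {pw01: 6.0}
noise_sigma: 0.3
seed: 11
drug_panel: {n_on_target: 2, n_off_target: 2}
```

`demo/pas.tsv` then contains:

```
pathway_id	case001	case002	case003	case004	case005	case006
pw01	3.620602984	3.862353483	3.933531174	3.842557998	3.633653021	3.637561725
pw02	0	0	0	0	0	0
pw03	0	0	0	0	0	-0.1929495942
```

The activated pathway scores near its noise-free value
5 · log10(6) ≈ 3.89 in every case sample, the quiescent pathways sit at 0
(one gene in one sample slips through the gate by chance, giving the small
negative entry). The ranking

```
drug	mean_ds	coverage
ON_01	3.755043398	NA
ON_02	3.755043398	NA
OFF_01	0	NA
OFF_02	0	NA
```

puts the drugs targeting the activated pathway on top (coverage is `NA`
because a DS table re-read from disk no longer carries per-drug pathway
counts). `pascore responders --ds demo/ds.tsv --drug ON_01 --rule positive`
flags all six case samples as predicted responders.

The same steps run as one pipeline with a manifest via
`pascore run --config config.yaml --outdir out/`, and
`pascore validate` / `pascore compare` compute the two cohort-level
statistics from responder tables.

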