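# radscreen

Analysis of **drug × radiation combination screens** in high-throughput
tumor-spheroid and monolayer assays: from raw well signals to
publication-style interaction tables that identify candidate
**radiosensitizers** — drugs that enhance ionizing-radiation cell kill beyond
what independent action predicts.

## Who this is for

Labs running plate-based radiosensitizer screens (fluorometric viability
assays such as the FMCA, GFP-reporter spheroid assays, clonogenic assays)
who need a reproducible, auditable pipeline for Bliss-independence synergy
calls, and method developers who want a simulator with known ground truth to
validate such pipelines.

## The model

For each condition (drug, concentration *c*, radiation dose *D*) the
pipeline computes, per independent experiment:

- **SI** (survival index, FMCA/GFP monolayer):
  `SI = (treated − blank) / (control − blank)` on mean well fluorescence;
- **AUTO SI** (spheroid GFP): endpoint fluorescence of a well divided by the
  *same well's* signal immediately before drug addition (self-normalized,
  no control term);
- **SF** (clonogenic survival fraction): colonies relative to untreated
  controls, without plating-efficiency correction.

Under **Bliss independence**, non-interacting treatments satisfy
`SI_e = SI_d × SI_r` (drug-only × radiation-only). The **interaction ratio**

```
ratio = SI_o / (SI_d × SI_r)
```

is formed within each experiment from that experiment's own arms; ratios
< 1 indicate synergy, > 1 antagonism. Per condition, the mean ratio over
n experiments is tested against 1 with a one-sample t-test (df = n − 1,
two-tailed, α = 0.05). Concentrations whose mean drug-only survival does
not exceed 25% are excluded (rendered "N/A"): when the drug alone kills
almost everything, the ratio is unstable and uninformative. In rendered
tables, ratios below 1 are bolded and significant ones carry `*`.

The bundled simulator generates screens with Hill drug-response curves,
linear-quadratic radiation survival `S(D) = exp(−αD − βD²)`, an interaction
factor ρ applied multiplicatively to combination survival (ρ = 1 ⇒ exact
additivity, so the pipeline's mean ratio estimates ρ), log-normal well and
between-experiment noise, duplicate wells, blanks and controls.

A small companion module scores semiquantitative **gamma-H2AX**
immunohistochemistry: percent positive cells → 0–4 plus signs, intensity
1–4, weighted score = plus count + intensity (0 when unexpressed).

## Worked example

Simulate a 5-experiment spheroid FMCA screen of two drugs — an OXPHOS
inhibitor with true synergy ρ = 0.8 at 6 Gy, and an additive antimetabolite —
then score it:

```bash
cat > config.json <<'EOF'
{
  "assay": "fmca", "culture": "spheroid",
  "drugs": {
    "oxphos_inhibitor": {"ec50": 4.0, "hill_slope": 1.2, "floor": 0.35},
    "antimetabolite": {"ec50": 400.0, "hill_slope": 1.0, "floor": 0.0}
  },
  "interaction": {"oxphos_inhibitor": 0.8},
  "design": {"n_experiments": 5,
             "concentrations": [100, 31.6, 10, 3.16, 1, 0.316, 0.1, 0.0316, 0.01],
             "doses": [6.0]},
  "noise": {"well_cv": 0.10, "experiment_cv": 0.05}
}
EOF
radscreen simulate --config config.json --seed 7 --out wells.csv
radscreen score wells.csv --out-table tables
```

which prints:

```
# 6 Gy
ratio	antimetabolite	oxphos_inhibitor
Highest conc.	**0.92***	**0.75***
	1.00	**0.78***
	**0.99**	**0.75***
	**0.99**	**0.74***
	1.01	**0.81***
	**0.97**	**0.79***
	**0.98**	**0.79***
	**0.93***	**0.78***
Lowest conc.	1.03	**0.78***
```

The synergistic drug's column recovers the simulated ρ = 0.8 (ratios
0.74–0.81, all bold + significant), while the additive drug scatters around
1.0 — the two asterisked cells in its column are the chance positives a 5%
two-tailed test produces. A machine-readable CSV twin of each table, a
per-experiment viability CSV and a run log are written alongside;
`radscreen report` adds dose-response figures, and `radscreen ihc-score`
scores gamma-H2AX observation tables.

From Python, the same pipeline is `radscreen.simulate.simulate_screen` →
`radscreen.viability.summarize_conditions` →
`radscreen.synergy.score_interactions`.

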