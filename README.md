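# cyp2c19-cea

An early decision-analytic cost-effectiveness model of a point-of-care
*CYP2C19* genotype test to guide antiplatelet prescribing after a first
ischaemic, non-cardioembolic stroke, from a UK NHS perspective.

Clopidogrel is a prodrug activated by the CYP2C19 enzyme. Roughly 25% of a
European-ancestry population carry a loss-of-function (LoF) allele (*2, *3
or *8), metabolise clopidogrel poorly, and face a higher risk of recurrent
stroke on it. A rapid bedside genotype test lets clinicians switch carriers
to modified-release dipyridamole plus aspirin (or aspirin alone). This
package estimates whether paying for that test (£60 plus £16.91 staff time)
buys health at an acceptable price.

The package is aimed at health-economics analysts: every input is explicit
in a validated YAML parameter file, and every stage (decision tree, Markov
cohort model, incremental economics, probabilistic and threshold
sensitivity analysis) is a plain Python function as well as a CLI command.

## Model

* **Decision tree** — allocates the cohort to regimens. Testing: non-carriers
  start clopidogrel (cascading to dipyridamole + aspirin, then aspirin, if
  not tolerated); carriers skip clopidogrel. No testing: everyone enters the
  clopidogrel cascade.
* **Markov cohort model** — five states (no additional stroke, one
  additional stroke, two or more additional strokes, vascular death,
  non-vascular death), annual cycles from age 67 to a lifetime horizon.
  From a living state with recurrent-stroke probability *p* and
  case-fatality *f*: *p·f* to vascular death, *p·(1−f)* advances the stroke
  count, and the stroke-free face the life-table mortality *q(age)*.
* **Genotype stratification** — the unstratified clopidogrel stroke risk
  *p̄* is the prevalence-weighted mean of the two genotype groups, so with
  non-carrier risk ratio RR and prevalence *f*<sub>LoF</sub>:
  *p*<sub>noLoF</sub> = RR·*p̄* and
  *p*<sub>LoF</sub> = *p̄*·(1 − (1 − *f*<sub>LoF</sub>)·RR)/*f*<sub>LoF</sub>.
* **Economics** — discounted (3.5%/yr) costs (£ 2021) and QALYs per
  strategy; ICER = ΔC/ΔQ with dominance labels;
  NHB = ΔQ − ΔC/λ; NMB = ΔQ·λ − ΔC at λ = £20,000/QALY;
  population totals over the 60,424 annual UK first ischaemic strokes.
* **Uncertainty** — PSA (beta/gamma/lognormal method-of-moments draws, one
  pipeline run per iteration, CEAC and cost-effectiveness plane) and
  one-way threshold analysis (bisection for the parameter value where
  per-patient NMB crosses zero).

## Worked example

```sh
cyp2c19-cea fixture --scenario paper_default --out inputs
cyp2c19-cea run --params inputs/parameters.yaml --life-table inputs/life_table.tsv --out base
```

prints (numbers produced by this code; unpublished appraisal inputs are
package assumptions, see `docs/methods.md`):

```
Incremental cost-effectiveness of CYP2C19 testing vs no testing
  willingness to pay: £20,000/QALY; cohort: 60,424 patients

  strategy        total cost (£)   total QALYs
  testing                 36,783         7.373
  no testing              38,531         7.204

  incremental cost:  £-1,749
  incremental QALYs: 0.169
  ICER:              dominant
  NHB per patient:   0.256 QALYs
  NMB per patient:   £5,124
  total NHB:         15,481 QALYs
  total NMB:         £309,626,171
  non-fatal strokes prevented: 7,856
  fatal strokes prevented:     1,964
```

Testing *dominates* (cheaper and more effective): switching the 25% of
carriers off clopidogrel averts recurrent strokes whose one-off and ongoing
care costs outweigh the test and the dearer replacement drug.

```sh
cyp2c19-cea psa --params inputs/parameters.yaml --life-table inputs/life_table.tsv \
    --out psa --n 1000 --seed 1
# PSA (1000 iterations, seed 1): P(cost-effective at £20,000/QALY) = 0.999, P(cost-saving) = 0.999

cyp2c19-cea threshold --params inputs/parameters.yaml --life-table inputs/life_table.tsv \
    --out thr --param rr_clopidogrel_no_lof --lower 0.702 --upper 1.3
# rr_clopidogrel_no_lof: threshold 0.988875 (baseline 0.702, NMB there £0.0060)
```

The threshold run says the non-carrier risk ratio could rise from 0.702 to
≈0.99 before testing stopped being cost-effective; varying dipyridamole
tolerance never flips the result at any level.

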