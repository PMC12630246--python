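# pvsignal

Case/non-case disproportionality analysis for spontaneous-report
pharmacovigilance databases.

Given a table of individual case safety reports (ICSRs), `pvsignal`:

1. **classifies** each report as a case or non-case by exact Preferred-Term
   matching against a user-supplied SMQ-style term list,
2. **samples** non-cases at a fixed ratio per case (default 4:1), uniformly
   without replacement from a seeded generator,
3. **expands** reports into drug mentions on the ATC hierarchy, collapsing
   fixed clinical combination products and applying a minimum-case filter,
4. **estimates** reporting odds ratios (ROR) from 2×2 tables with the
   Haldane zero-cell correction and Woolf (log-method) 95% confidence
   intervals, at ATC2 (class) and ATC5 (substance) levels, under a
   sibling-within-class or all-other-drugs comparator,
5. **flags** signals by a-priori criteria (ROR ≥ 2, CI lower bound > 1,
   ≥ 5 case mentions) and produces cohort descriptive statistics
   (Pearson χ² without continuity correction, pooled-variance t test).

A synthetic ICSR generator with planted drug–event associations makes every
stage testable end-to-end with no real pharmacovigilance data and supports
type-I-error / power simulations for the signal criteria.

## CLI

```bash
# generate a synthetic database + term list from the bundled preset
pvsignal simulate --out icsr.csv --truth-out truth.json --smq-out smq.txt --seed 1

# classify / sample individual stages
pvsignal classify --reports icsr.csv --smq smq.txt
pvsignal sample --reports icsr.csv --smq smq.txt --ratio 4 --seed 11 --out sampled.txt

# full pipeline run (flags or --config run.yaml)
pvsignal analyze --reports icsr.csv --smq smq.txt --output-dir out --seed 11
```

`analyze` writes `results.tsv` (per-entity cells, ROR, CI, signal flag),
`descriptives.tsv` (cohort table with test statistics), the sampled
non-case id list, and a `manifest.json` (input hashes, config, seed) that
fully determines every output byte.

### File formats

- **ICSR CSV** — one row per report, columns `report_id, report_date,
  reporter_hcp, sex, age_years, outcomes, drug_atc5_list, drug_inn_list,
  reaction_pt_list`. List-valued cells use a `|` secondary delimiter
  (backslash-escaped). Missing values: empty cells; sex `U` is read as
  missing; an empty `outcomes` cell means the outcome classification is
  missing.
- **SMQ term list** — plain text, one Preferred Term per line, `#` comments.
- **Combination rules CSV** — columns `combined_label, member_match`, one
  member (ATC5 code or name glob) per row.

## API sketch

```python
import pvsignal as pv

reports = pv.read_reports("icsr.csv")
smq = pv.load_smq("smq.txt", name="Acute Renal Failure", scope="narrow")
cases, pool = pv.classify_all(reports, smq)
sampled = pv.sample_noncases(pool, len(cases), ratio=4, seed=11)
mentions = pv.expand_mentions(cases, sampled)
table = pv.build_table(mentions, "B01AE07", level=5)
result = pv.compute_ror(pv.haldane_adjust(table))
```
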