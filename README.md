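# teabag-index

Tools for computing and auditing the **Tea Bag Index (TBI)** — the
standardised litter-decomposition proxy based on paired ~90-day burials of
green tea (fast decomposing) and rooibos (slow decomposing) mesh bags —
and for testing when its parameters can be trusted.

The TBI rests on the two-pool asymptotic exponential decay model

```
m(t) = a · e^(−k·t) + (1 − a)
```

where `m(t)` is the remaining mass fraction at day `t`, `a` the
decomposable (labile) fraction and `1 − a` the asymptote. Green-tea mass
loss at harvest, scaled to its hydrolysable fraction `H_g`, gives the
stabilisation factor `S = 1 − loss_g / H_g`; transferring `S` to rooibos
gives its decomposable fraction `a_r = H_r (1 − S)`, and inverting the
curve at the observed rooibos remaining mass `m` gives the initial
decomposition rate `k = ln(a_r / (m − (1 − a_r))) / t`.

That inversion is only meaningful while the rooibos bag is still well
above its asymptote. The package therefore also provides:

* **`fitting`** — nonlinear least-squares fits of the decay model to
  mass-loss time series (`k_real`, `asymptote_real`), with series
  truncation to study incubation-length effects;
* **`diagnostics`** — validity flags (negative `S`, mass margin ≤ 10 % of
  initial dry mass, incubation outside 45–135 days, asymptote reached,
  mass gain), cohort filtering, the green→rooibos asymptote-transfer
  regression, and predicted-vs-observed rate comparisons stratified by
  mass margin;
* **`synthetic`** — a three-pool forward simulator (labile + stabilised +
  optionally leaking recalcitrant pool, additive Gaussian noise) for
  generating test data with controlled assumption violations;
* **`tbi`** — a command line tying these together.

Intended users: ecologists running tea-bag or litter-bag incubations who
want TBI parameters *with* validity auditing, and methodologists studying
the behaviour of decomposition-curve estimators.

## Worked example

```python
from teabag import HarvestRecord, tbi_from_pair, audit_pair

green = HarvestRecord("g1", "green", 2.000, 0.653, 90, pair_id="site-A")
rooibos = HarvestRecord("r1", "rooibos", 2.000, 1.500, 90, pair_id="site-A")
result = tbi_from_pair(green, rooibos)
print(f"S_TBI        = {result.s_tbi:.4f}")
print(f"a_rooibos    = {result.a_rooibos:.4f}")
print(f"k_TBI        = {result.k_tbi:.6f} per day")
print(f"mass margin  = {result.mm_rooibos_pct:.2f} %")
print(f"flags        = {sorted(f.value for f in result.flags)}")
report = audit_pair(result)
print(f"usable       = {report.usable}")
```

prints

```
S_TBI        = 0.2001
a_rooibos    = 0.4415
k_TBI        = 0.009280 per day
mass margin  = 19.15 %
flags        = []
usable       = True
```

The green bag lost 67.35 % of its 2 g, so about 20 % of its hydrolysable
pool stabilised (`S_TBI ≈ 0.20`). Transferring that stabilisation to
rooibos predicts a decomposable fraction of 0.4415 (asymptote 0.5585);
the rooibos bag, still at 75 % of its initial mass on day 90, sits
19.15 percentage points above that asymptote — a comfortable mass
margin — giving a well-defined initial rate of 0.00928 day⁻¹ and a pair
usable under all validity checks.

From the shell, the same computation over a whole harvest table:

```sh
tbi compute --harvest harvest.csv --out results/
tbi fit --series series.csv --out fits.csv          # k_real, asymptote_real
tbi simulate --reps 50 --seed 1 --out recovery.csv  # parameter-recovery MC
```

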