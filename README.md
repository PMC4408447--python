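# aldorecur

Statistical and biophysical toolkit for studies of recurrent mutations in
early-onset primary aldosteronism (PA).

When the same rare protein-altering variant — here the paradigm case is a
gain-of-function substitution in *CACNA1H*, encoding the T-type calcium
channel Ca_V3.2 expressed in the adrenal zona glomerulosa — turns up in
several unrelated kindreds, four quantitative questions follow, and this
package implements the analysis for each:

1. **Could the recurrence be chance?**  Binomial statistics for repeated de
   novo hits at one base (corrected for the 24.75 Mb protein-altering exome
   target) and for additional carriers at an assumed allele frequency, with
   their product as the combined chance probability
   (`aldorecur.recurrence`).
2. **Who is affected?**  Aldosterone:renin ratio (ARR) screening with
   censored laboratory values propagated by interval arithmetic, plus
   cohort-level variant searches: recurrent novel variants and Fisher-exact
   gene burden against a control cohort (`aldorecur.labs`,
   `aldorecur.variants`).
3. **Is the mutation identical by descent?**  The maximal haplotype interval
   shared by carriers around the focal variant (phased scan and the
   conservative unphased homozygous-discordant bound), and a
   maximum-likelihood estimate of generations to the carriers' most recent
   common ancestor from the length of retained ancestral haplotype — a
   recombination-clock estimator in the ESTIAGE family
   (`aldorecur.haplotype`).
4. **What does the mutation do to the channel?**  Whole-cell voltage-clamp
   analysis: peak I–V, Boltzmann activation fits I(V) = G_max(V−V_rev)/(1 +
   e^((V½−V)/k)), mono-exponential inactivation and recovery kinetics,
   window current, current density, and non-stationary noise analysis via
   σ² = i⟨I⟩ − ⟨I⟩²/N (`aldorecur.ephys`).

Every stage is paired with a generator in `aldorecur.simulate` — a
Hodgkin–Huxley-style m²h channel simulator (deterministic and stochastic), a
descendant-haplotype simulator, and toy cohort tables — so the entire
pipeline is testable end-to-end without any external data.

## Worked example

```python
import numpy as np
from aldorecur import recurrence, labs, haplotype, ephys, simulate

# 1. chance probability of the observed recurrence
p_dn = recurrence.p_recurrent_de_novo(n_cases=41, mu_dn=1.4e-8, target_bp=24.75e6)
p_add = recurrence.p_additional_carriers(n_subjects=38, k=3, allele_freq=1e-5)
print(f"{p_dn:.2g}  {p_add:.2g}  {recurrence.combined_recurrence(p_dn, p_add):.2g}")
# 4e-06  8.4e-12  3.4e-17

# 2. ARR with a censored renin: aldosterone 20 ng/dl, PRA below 0.1
arr = labs.compute_arr(labs.CensoredMeasure(20), labs.CensoredMeasure(0.1, "below"))
print(labs.round_ratio(arr))
# >200

# 3. mutation age from simulated carrier haplotypes (100 generations deep)
mmap, ancestral = simulate.default_marker_map(seed=42)
haps, obs = simulate.simulate_descendant_haplotypes(ancestral, mmap, g=100,
                                                    n_carriers=4, seed=1)
est = haplotype.estimate_age(obs, mmap)
print(est.g_hat, (est.ci_low, est.ci_high))
# 188 (77, 1174)

# 4. fitted activation midpoint of the mutant channel
iv = ephys.peak_iv(simulate.iv_ensemble(simulate.default_params("M1549V")))
print(round(ephys.fit_activation(iv).v_half, 1))
# -44.2
```

The first line is the chance probability that two or more of 41 probands
carry a de novo hit at the same protein-altering base (~4×10⁻⁶), the
probability that 3 of 38 further unrelated subjects carry a 10⁻⁵-frequency
allele (~8.4×10⁻¹²), and their product (~3.4×10⁻¹⁷).  The ARR `>200` is a
lower bound because the renin was below its detection limit.  The age
estimate recovers the simulated 100-generation depth within its 95 %
profile-likelihood CI.  The activation fit reproduces the hyperpolarized
midpoint of the mutant channel, −44.2 mV versus −38.9 mV for wild type.

A command-line interface mirrors the library:

```bash
aldorecur recurrence --n-denovo 41 --mu 1.4e-8 --target-mb 24.75 --n-inherited 38 --k 3 --freq 1e-5
aldorecur screen labs.csv
aldorecur burden --case 5/40 --ctrl 0/724 --genes 20000
aldorecur age --map chr16.map --haps carriers.tsv --freqs eur.tsv --focal-bp 10000000
aldorecur ephys activation traces.tsv --protocol protocol.yaml
```

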