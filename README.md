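# thalabeta

Alpha-rhythm slowing — the drift of the dominant 8–13 Hz EEG peak
toward lower frequency and power — is a classic electrophysiological
marker of Alzheimer's disease. `thalabeta` is a small simulator for
studying one candidate mechanism: amyloid-β deposition impairing the
inhibitory thalamic reticular nucleus (TRN) and thereby detuning the
thalamocortical loop that generates the alpha rhythm. It is aimed at
computational-neuroscience users who want a reproducible, scriptable
version of this model and its spectral readouts.

## Model

Three neural-mass populations — retinal relay, thalamocortical relay
nucleus (TCR), and TRN — each follow a critically damped second-order
synaptic kernel with a logistic rate function
S(v) = 2e₀/(1 + e^(−ν(v−s₀))):

    ẍ_ret = (H_e/τ_e)·P(t)                   − (2/τ_e)ẋ_ret − x_ret/τ_e²
    ẍ_tcr = (H_e/τ_e)·S(C₃x_ret − C₂x_trn)   − (2/τ_e)ẋ_tcr − x_tcr/τ_e²
    ẍ_trn = (H_i/τ_i)·S(C₁x_tcr)             − (2/τ_i)ẋ_trn − x_trn/τ_i²

P(t) is Gaussian white noise (mean μ_r, variance φ_r) standing in for
sensory input; the analysed signal is V = C₃x_ret − C₂x_trn.

Amyloid load enters as a PET SUVR scalar β_a through a calibrated
decreasing logistic S1 whose reciprocal sets the TRN time constant:

    τ_i(β_a) = 1/S1(β_a) ∈ [14.29, 50] ms,   clamped at 14.29 ms below
                                             the clinical cutoff β_a = 1.4

Raising β_a lengthens τ_i, weakens effective TRN inhibition's tuning of
the loop, and slows and flattens the alpha peak. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Tabulate the amyloid → τ_i mapping:

```sh
$ thalabeta map-tau --grid 1.4:2.6:0.3
beta_a,tau_i_ms,severity
1.4,14.986,moderate
1.7,16.6744,moderate
2,21.585,moderate_severe
2.3,31.405,severe
2.6,41.6933,severe
```

Simulate a healthy brain region and a severely affected one
(20 repeats of 30 s each, ~3 s of compute per condition):

```python
from thalabeta import (ModelParameters, SimulationConfig, SpectralConfig,
                       calibrate, run_repeats, summarize_traces, tau_i_of_beta)

cal = calibrate()
cfg = SimulationConfig(duration=30.0, dt=1e-3, transient=2.0, n_repeats=20, seed=0)
for beta in (0.001, 3.00):
    tau = float(tau_i_of_beta(beta, cal))
    params = ModelParameters(mu_r=86.0, tau_i=tau)
    res = run_repeats(params, cfg)
    s = summarize_traces(res.traces, SpectralConfig(fs=cfg.fs))
    print(f"beta_a={beta}: tau_i={tau:.2f} ms, "
          f"peak={s.peak_power:.3g} mV^2/Hz at {s.dominant_freq} Hz")
```

prints

```
beta_a=0.001: tau_i=14.29 ms, peak=968 mV^2/Hz at 10.75 Hz
beta_a=3.0: tau_i=48.13 ms, peak=7.32e-05 mV^2/Hz at 8.0 Hz
```

— the amyloid-negative region oscillates strongly at 10.75 Hz, while
at severe load the alpha peak has collapsed by seven orders of
magnitude and slid to the bottom of the band: alpha slowing. The same
pipeline is available from the shell (`thalabeta simulate --beta 3.0
--mu 86`, then `thalabeta analyze --timeseries ...`), and the
parameter sweeps behind the full experiments as `thalabeta sweep-beta
/ sweep-c1 / sweep-mu`, each writing a tidy CSV plus a manifest of
every effective parameter and seed.

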