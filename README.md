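# nbratchet

A Brownian-ratchet model of how Y-family DNA polymerases (Dpo4, Dbh,
Pol ι/η — the low-fidelity, lesion-bypassing translesion enzymes) move
along their DNA template, implemented as a tested Python library plus a
small CLI.

## The model

The polymerase is an overdamped Brownian sphere (Stokes drag
Γ = 6πηR ≈ 9.4 × 10⁻¹¹ kg s⁻¹, D = k\_BT/Γ) diffusing on a
two-dimensional energy landscape

```
U(x, r) = V(x) · [2 exp(−r/r_d) − exp(−2r/r_d)]
```

where `x` runs along the template (site spacing p = 0.34 nm), `r` is the
separation from the DNA, and `r_d = 0.5` nm is half the Debye screening
length.  `V(x)` is a piecewise-linear sawtooth whose well depths at the
pre- and post-translocation registers, E\_n and E\_{n+1}, are set by how
many template bases / backbone segments the enzyme's two DNA-binding sites
cover in each register, plus a uniform electrostatic offset E₀.  The
enzyme hops thermally between the two registers; a dNTP can bind only in
the post-translocation register and, once bound, sterically blocks the
backward hop — thermal motion is *rectified by nucleotide binding* rather
than powered by it.

From this landscape the package computes, via the exact double-integral
mean-first-passage-time (MFPT) formula
`T = D⁻¹ ∫ e^{βV(y)} ∫ e^{−βV(z)} dz dy`:

- **moving times** between registers (quadrature + an exact closed form),
- **dissociation times** T_d from the Morse escape potential and the
  **processivity** N_p = T_d/T_p2 (nucleotides per binding event, with
  T_p2 = 0.065 s the vulnerable window per cycle),
- **dwell ratios** T_n/T_{n+1} = exp[(ΔE + F·p)/k_BT] under a backward
  load F, the **binding-rate factor** R(F) = (1+ρ(0))/(1+ρ(F)), and the
  **synthesis rate** k(F, S) = k_c·S/(S + K_m/R(F)),
- stochastic cross-checks: an Euler–Maruyama Langevin integrator on
  U(x, r) and an event-driven Monte Carlo of the incorporation cycle.

Because processivity depends exponentially on the binding affinity, a
~5 k_BT loss of duplex contact at a lesion collapses N_p from ~100 to ~1 —
which is why Dpo4 shrugs off lesions that strand Dbh, and why the model's
load response separates Y-family enzymes (ΔE ≥ 0, strong force
sensitivity) from replicative ones (ΔE ≈ −5 k_BT, almost none).

## Worked example

```python
>>> import nbratchet as nb
>>> env = nb.make_environment()          # 300 K, water, R = 5 nm
>>> f"{env.drag_coefficient_kg_per_s:.1e}"
'9.4e-11'

>>> p = nb.get_preset("dpo4")            # E_n − E_{n+1} = 3 kT, E_r = 20.8 kT
>>> res = nb.processivity(p.energies, p.kinetics, p.geometry, p.environment,
...                       "dpo4_like")
>>> round(res.t_d_s["site_n1"], 2), round(res.n_p, 1)
(7.88, 121.2)
```

Dpo4 stays bound for ~7.9 s and incorporates ~120 nucleotides per binding
event.  At a lesion (one fewer duplex contact, `scenario="lesion_at_n"`)
the same call gives N_p ≈ 1.0: synthesis turns distributive.  Moving
times and force response:

```python
>>> geom = nb.Geometry()
>>> nb.moving_time(22, 17, geom, env).mean_time_s   # forward hop, s
0.01117...
>>> nb.moving_time(17, 22, geom, env).mean_time_s   # backward hop, s
9.74e-05...
>>> nb.binding_rate_factor(3.0, 20.0, geom, env)    # Dpo4 under 20 pN load
0.201...
>>> nb.binding_rate_factor(-5.0, 20.0, geom, env)   # replicative enzyme
0.972...
```

The forward hop takes ~11 ms against the 22 k_BT well, the backward hop
~0.1 ms; a 20 pN backward load cuts Dpo4's dNTP-binding rate five-fold
but leaves a replicative polymerase essentially untouched.

The same analyses are scriptable from the shell:

```bash
nbr processivity --preset dpo4
nbr figure fig10 --out-dir out/       # R(F) curves for six ΔE values
nbr run config.yaml                   # batch runs from a YAML config
```

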