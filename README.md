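# ionqt

Quantum tunneling of lithium ions through the **closed** gates of
voltage-gated sodium channels, and what that does to the resting membrane
potential.

Classical electrophysiology struggles to explain lithium's depolarizing
action: at resting state lithium should share sodium's tiny leak
permeability, which cannot produce the observed ~26 mV depolarizations at
100 mmol/L, any effect at the ~1 mmol/L therapeutic range, or the
different potencies of the Li-6 and Li-7 isotopes.  `ionqt` implements a
quantum-transport alternative: the closed intracellular gate is an energy
barrier that ions cross by tunneling, giving the membrane a lithium
conductance that is continuous in the gate parameters, strongly
mass-dependent, and large enough to depolarize.  The package is for
computational electrophysiologists and biophysicists who want to evaluate,
sweep, or test this model.

## Model

The closed gate (energy `g`, length `w`) is a linear ramp
`U(x) = g·x/w`.  An ion of mass `m` and kinetic energy `KE < g` tunnels
through with probability

```
T_Q = exp( − √(8m)/ħ · (2w/3g) · (g − KE)^(3/2) )
```

Extracellular ions reach the gate with `KE = q·Vm + (3/2)k_B·T`
(membrane-voltage fall plus thermal energy); intracellular ions carry the
thermal term only, so the tunneling flux is strongly inward.  A single
closed channel then conducts `C_Q = (q²/h)·T_Q`, and a membrane with
channel density `D` has `MC_Q = D·C_Q` (mS/cm²).  Inserting `MC_Q` for
the lithium term of the Goldman–Hodgkin–Katz balance

```
[K]e·MC_K + [Na]e·MC_Na + [Li]e·MC_Q^E(Vm)
    = e^(−F·Vm/RT) · ([K]i·MC_K + [Na]i·MC_Na + R·[Li]e·MC_Q^I)
```

makes the equation transcendental (the extracellular conductance depends
on the `Vm` being solved for); it is solved by bracketed root-finding.
Because the tunneling exponent scales with `√m`, the Li-6/Li-7
transmission ratio `exp(Δc·(L/G)·(G−KE)^(3/2))` reaches values far above
the classical bound of 1.006–1.17 — the model's experimentally testable
signature.  Gate parameters are usually quoted in scaled units
`G = g/10⁻²⁰ J` and `L = w/10⁻¹⁰ m`.

## Worked example

```python
>>> import ionqt as q
>>> li7 = q.get_ion("Li-7")
>>> gate = q.GateBarrier.from_scaled(G=5, L=1)         # g=5e-20 J, w=1e-10 m
>>> ke = q.extracellular_kinetic_energy(0.087, li7)    # |Vm| = 87 mV
>>> tq = q.tunneling_probability(li7, gate, ke)
>>> tq.probability
2.9696356882906215e-09
>>> q.membrane_conductance(li7, tq, q.ChannelPopulation(1e11, gate))
11.522186470567613
>>> sol = q.quantum_ghk_solve(q.MembraneBath(Li_out=100, li_ratio=2),
...                           li7, q.ChannelPopulation(1e11, gate))
>>> round(sol.Vm, 3)
0.055
```

A Li-7 ion hitting the closed gate at −87 mV tunnels with probability
~3×10⁻⁹; at 10¹¹ channels/cm² that already amounts to 11.5 mS/cm² of
lithium membrane conductance — far above the 0.005 mS/cm² sodium leak.
Feeding it back into the GHK balance, 100 mmol/L extracellular lithium
shifts the resting potential from −87 mV to −55 mV: a 32 mV
depolarization, where the classical leak model manages at most 10 mV.
The same pipeline runs from the shell:

```
$ ionqt ghk quantum --ion Li-6 --li-out 1 --density 1e11
$ ionqt isotope-ratio --side extra --G 5 --L 1 --Vm 0.087
$ ionqt reproduce --all
170 pass, 0 fail, 2 flagged
```

`ionqt reproduce` recomputes all 36 published tables of the model
(probabilities, conductances, classical and quantum potentials,
depolarization degrees, isotope ratios) from the packaged fixture of
printed values; the two flagged cells are known internal inconsistencies
of the source tables and are reported, never asserted.

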