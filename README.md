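# notchemt

A simulator for the coupled **Notch-Delta-Jagged / EMT** regulatory
circuit: a single-cell ODE core with brute-force bifurcation analysis,
and a hexagonal-lattice tissue simulator with pattern metrics.

## The scientific problem

During cancer metastasis, carcinoma cells can undergo a *partial*
epithelial-mesenchymal transition (EMT) and migrate collectively as
clusters of hybrid epithelial/mesenchymal (E/M) cells — the phenotype
associated with clusters of circulating tumour cells.  Which
cell-cell signals let a cluster of cells hold this intermediate state?
Notch signalling is the natural suspect, but its two ligand families
act oppositely: Delta-mediated signalling is *lateral inhibition*
(neighbours adopt opposite fates, producing checkerboard-like
patterns), while Jagged-mediated signalling is *lateral induction*
(neighbours adopt the same fate, producing clusters).

`notchemt` implements a mechanistic model of this question for
computational biologists: each cell couples the Notch-Delta-Jagged
signalling module (trans-activation, cis-inhibition, NICD release) to
the miR-34/SNAIL + miR-200/ZEB tristable EMT switch, with the
cross-links NICD → SNAIL, miR-34 ⊣ Notch/Delta and miR-200 ⊣ Jagged.
Regulation uses shifted Hill functions
H(X) = (1 + λ(X/X₀)ⁿ)/(1 + (X/X₀)ⁿ) and a multi-site
binomial-occupancy model for microRNA-mRNA interactions.  The tissue
level runs one copy of the circuit per cell of a hexagonal lattice,
with each cell's external ligand/receptor assembled from its six
neighbours.

The model reproduces, per the packaged default parameters: a bistable
Sender/Receiver switch for epithelial cells; EMT staging
E → E/M → M under rising external Jagged; and the central tissue-level
contrast — Jagged-dominated signalling transiently organises hybrid
E/M cells into large clusters that external soluble Jagged stabilises,
while Delta-dominated signalling does not aggregate.

## Worked example

```python
import notchemt as ne

params = ne.default_parameters()
env = ne.Environment(j_ext=600.0, n_ext=5000.0)   # moderate external Jagged
states = ne.find_stable_states(env, params, n_starts=24, seed=1)
for s in states:
    print(ne.classify_emt(s), ne.classify_sr(s),
          f"N={s[0]:.0f} D={s[1]:.0f} J={s[2]:.0f} NICD={s[3]:.1f} miR200={s[4]:.0f}")
```

prints

```
E S N=34 D=92 J=24 NICD=1.6 miR200=39007
E R N=423 D=3 J=46 NICD=20.3 miR200=33993
```

two stable epithelial states at the same operating point: a **Receiver**
(high Notch, Delta shut off by NICD) and a **Sender** (high Delta, low
Notch) — the bistable switch behind checkerboard patterning.  A tissue
run takes a few seconds:

```python
lat = ne.build_lattice(16, 16)                      # periodic hexagonal grid
p = params.with_overrides(g_delta=20.0, g_jagged=70.0)   # Jagged-dominated
cfg = ne.TissueConfig(params=p, t_end=240.0, dt=0.2, seed=1,
                      snapshot_times=(120.0,))
s0 = ne.random_initial_states(lat, cfg.init_ranges, seed=1)
at120, at240 = ne.simulate_tissue(lat, s0, cfg)
print([round(f, 2) for f in ne.phenotype_fractions(at120)],
      ne.cluster_components(at120, "non-E")[:1],
      [round(f, 2) for f in ne.phenotype_fractions(at240)])
```

```
[0.34, 0.66, 0.0] [168] [1.0, 0.0, 0.0]
```

At 120 h two-thirds of the cells are hybrid E/M, gathered into a single
168-cell cluster; with no external signal the cluster is transient and
the tissue is fully epithelial again by 240 h.  Raising soluble Jagged
(`sj_ext=4000`) or the EMT inducer (`i_ext=70`) in a continuation run
stabilises or deepens the transition instead.

A command-line driver wraps the same library:

```bash
notch-emt simulate --gd 20 --gj 70 --size 16 --tend 120 --seed 1 --out runs/
notch-emt analyze runs/tissue_t120.csv
notch-emt experiment fig4 --size 20 --out runs/
```

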