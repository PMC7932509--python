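# shhagg

A deterministic model of **sonic hedgehog (Shh) aggregate formation on a
producing cell**, for systems biologists studying how morphogen carriers
shape the size distribution of released signalling particles.

Shh is lipid-modified and sticks to the membrane of the cell that makes it;
to travel, it must be packaged into aggregates. Three mechanisms compete for
the monomers a cell produces:

* **multimerisation** — free monomers and multimers coagulate pairwise,
* **HSPG recruitment** — heparan sulfate proteoglycans scaffold small
  multimers (2–10 monomers each) into larger aggregates,
* **lipoprotein loading** — lipoprotein particles take up monomers one at a
  time.

Every cell-associated species can also *disperse* — detach into an inert
pool representing diffusion away from the cell. The model asks which
mechanism forms which aggregate sizes, and why the resulting size–frequency
distribution looks exponential, as it does in microscopy of Shh clusters.

## The model

Let $M_n$, $H_j$, $L_k$ be the counts (per cell) of free multimers with $n$
Shh, HSPG-bound aggregates with $j$ Shh, and lipoproteins carrying $k$ Shh.
Mass-action kinetics give a Smoluchowski coagulation system with constant
kernel, carrier recruitment, constant sources and first-order dispersal:

$$\frac{dM_n}{dt} = \tfrac12 k_{\mathrm{mult}}\!\!\sum_{i+j=n}\!\! M_i M_j
  - k_{\mathrm{mult}} M_n \!\sum_j M_j
  - k_{\mathrm{hspg}} M_n \!\sum_j H_j \,[2 \le n \le 10]
  - k_{\mathrm{lipo}} M_n \!\sum_k L_k \,[n \le 1]
  - d\, M_n + s_M [n{=}1]$$

with analogous gain terms for $H_j$ and $L_k$, sources
$s_H = r_H s_M$ and $s_L = r_L s_M$ for empty carriers, and an absorbing cap
at 200 monomers per aggregate. Dispersed copies of every species accumulate
without reacting. The full network is ~1,200 ODEs, integrated with a BDF
stiff solver and an analytic sparse Jacobian.

On top of the simulator the package provides: mechanism-resolved
size–frequency distributions and percentage breakdown tables (entity
counting: one loaded carrier or free multimer = one entity), exponential
shape fits, dispersed aggregate:monomer ratios, a registry of variant
scenarios (dispersal removal, single-mechanism runs, rate/source sweeps,
relaxed recruitment rules), carrier-source calibration tools, and
Stokes–Einstein diffusion estimates per mechanism and size.

## Worked example

```sh
shhagg -v simulate examples/baseline.yaml -o out/
```

runs the baseline 24-hour simulation plus a dispersal-free variant and
writes breakdown tables, raw counts, a share time-course, fit summaries,
diffusion estimates and a reproducibility manifest. The log reports

```
scenario baseline: cell fit lambda=0.1578 R2=0.9872
scenario no_dispersal: cell fit lambda=0.1998 R2=0.9606
```

i.e. both distributions decay near-exponentially with size (decay rate
λ ≈ 0.16 per monomer at baseline). The first rows of
`out/baseline_cell_breakdown.csv`:

```
mechanism,1,2,3,4,5,...
monomers,21.50,0.00,0.00,0.00,0.00,...
multimers,0.00,5.09,2.41,1.43,0.95,...
```

read: after 24 h, 21.5% of all cell-associated entities are free monomers,
5.09% are dimers, and so on; each table sums to 100. The same analysis from
Python:

```python
import shhagg as sa

traj = sa.integrate(sa.ModelConfig(), sa.ParameterSet(), t_end=1440.0)
cell = sa.size_distribution(traj.snapshot(1440.0), traj.index, sa.CELL)
print(sa.mechanism_shares(cell))
# {'monomers': 21.50, 'multimers': 17.41, 'hspg': 20.55, 'lipoproteins': 40.55}
print(sa.aggregate_monomer_ratio(traj, (0.0, 1440.0)))   # 2.62
print(100 * sa.fraction_leq_size(cell, 40))              # 96.5
```

The dispersed pool releases aggregates and monomers at about 2.6:1 over the
first 24 hours (rising to ~3.6:1 in the final hour), and 96.5% of
cell-associated aggregates contain 40 monomers or fewer — which is why
tables report sizes 1–40 plus a single `>40` bucket.

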