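# netprox

Network-proximity drug repurposing screens on protein–protein interactomes.

Given an interactome, a table of drug–target interactions, and disease gene
modules (e.g., differential-expression or literature-derived gene sets),
`netprox` asks for each (drug, module) pair whether the drug's targets sit
closer to the module in the network than expected by chance — a signature of
drugs that may perturb the module's biology and are therefore repurposing
candidates. It also scores tissue expression specificity of genes, curates
drug-target inputs by binding affinity, and exports three annotated
subnetwork views for visualization.

## The statistic

For a drug's target set *A* and a disease module *B*, the **closest network
proximity** is

    <d_AB> = ( Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b) ) / (|A| + |B|)

with *d(a,b)* the unweighted shortest-path length. Because hubs are close to
everything, the raw distance is standardized against a **degree-preserving
permutation null**: both sets are resampled (each gene replaced by a random
gene from its degree bin) in 1000 random experiments, and

    z_d = (d − d̄) / σ_d

with d̄, σ_d the mean and standard deviation of the permuted distances. A
pair is called **significantly proximal** when z < −1.5 and the empirical
one-sided p < 0.05. Overlap coefficient C = |A∩B| / min(|A|,|B|) and Jaccard
index J = |A∩B| / |A∪B| quantify direct set overlap.

Supporting computations:

* **Tissue specificity** — a gene is *expressed* in a tissue when its CPM is
  ≥ 0.5 in strictly more than 90% of that tissue's samples; its specificity
  is z_E(i,t) = (E(i,t) − ⟨E(i)⟩) / δ_E(i) across tissues.
* **Curation** — drug–target interactions are kept when they are biophysical
  measurements (Ki, Kd, EC50, IC50) of ≤ 10 μM on human proteins; non-human
  targets enter only through an explicit ortholog table.
* **Views** — EGO (brain-filtered neighborhood of a gene), LCC (largest
  connected component of a module), and MOA (targets ∪ module induced
  subgraph, the interactions through which the drug may act), exported as
  GraphML or a documented JSON dialect.

## Worked example

Generate a synthetic screen fixture with one planted proximal pair (module
MOD0 is a connected cluster; DRUG0's targets are its direct neighbors), then
screen 5 drugs against 4 modules:

```python
from netprox import fixtures, load_interactome, screen

manifest = fixtures.make_screen_fixture("fx/", seed=1)
inter = load_interactome(manifest["graph"])
drugs, sets = fixtures.screen_fixture_objects(manifest)
df = screen(inter, drugs, sets, n_perm=1000, rng_seed=1)
print(df[df["significant"]][["drug_id", "set_id", "d_observed", "z", "p"]])
```

Output:

```
drug_id set_id  d_observed         z        p
  DRUG0   MOD0    1.277778 -2.431889 0.013986
```

The planted pair — and only it — is flagged: DRUG0's targets average 1.28
hops from MOD0, 2.4 null standard deviations closer than degree-matched
random sets (p = 0.014 over 1000 permutations). The same run from the shell:

```sh
netprox screen --graph fx/edges.tsv --drugs fx/drug_targets.tsv \
    --sets fx/modules.gmt --n-perm 1000 --seed 1 --out screen.tsv
netprox moa --graph fx/edges.tsv --drugs fx/drug_targets.tsv --drug-id DRUG0 \
    --sets fx/modules.gmt --set-id MOD0 --format json --out moa.json
```

## Layout

* `src/netprox/graphio.py` — interactome / GMT / view I-O and schemas
* `src/netprox/proximity.py` — closest distance, permutation z, the screen
* `src/netprox/specificity.py` — expressed calls and specificity z-scores
* `src/netprox/curation.py` — affinity filtering and ortholog mapping
* `src/netprox/subnets.py` — EGO / LCC / MOA annotated views
* `src/netprox/fixtures.py` — synthetic data with planted ground truth
* `src/netprox/cli.py` — the `netprox` command-line interface
* `docs/methods.md` — modelling choices, parameters, and limitations
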