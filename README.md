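# frustnet

Boolean-network analysis of genetic frustration in somatic-cell
reprogramming.

`frustnet` is for computational biologists studying induced cell-fate
transitions (e.g. MEF → iPSC reprogramming) with Boolean models of gene
regulatory networks. It simulates asynchronous threshold dynamics on a
signed regulatory network, quantifies global and per-gene *frustration*
along reprogramming trajectories, runs in-silico overexpression/knockdown
screens, embeds steady-state ensembles into a phenotypic landscape, and
binarizes expression matrices so that experimental time courses can be read
against the model.

## Model

A cell state is a binary vector **x** ∈ {0,1}^N over the network's gene
roster. Gene *i* updates by the threshold rule

```
x_i(t+1) = 1  if Σ_j A_ij x_j > 0
           x_i(t)  if Σ_j A_ij x_j = 0
           0  if Σ_j A_ij x_j < 0
```

with A_ij = ±1 the sign of the regulatory edge *j → i*. Updates are
asynchronous — one gene, drawn uniformly among those mandated to flip, per
step — and a state with no such gene is a fixed point (a stable phenotype).

Consistency of a state with the regulatory wiring is scored by a
spin-glass-style pseudo-energy over spins s_i = 2x_i − 1:

```
E(x) = − Σ_edges A_ij s_i s_j          (global frustration)
E_i(x) = − Σ_{j→i} A_ij s_i s_j        (single-site / local frustration)
```

with Σ_i E_i = E exactly. The *driving force* DF(x) counts genes whose bit
disagrees with the rule's mandate (DF = 0 ⇔ fixed point). Phenotype scores
Φ_PS and Φ_EM (pluripotent-vs-somatic, epithelial-vs-mesenchymal) count
active positive markers minus active negative markers over a curated
33-gene panel; perturbations clamp genes to 1 (overexpression) or 0
(knockdown) for the whole simulation.

A built-in synthetic generator provides random signed networks, networks
with *planted* minimally frustrated attractor pairs, bimodal expression
matrices with dropout, and an 88-gene / 387-edge reprogramming stand-in
network with somatic-mesenchymal (SM) and pluripotent-epithelial (PE)
anchor phenotypes, so the entire pipeline runs without any external data.

## Worked example

```python
import numpy as np
import frustnet as fn

grn, anchors = fn.reprogramming_network()   # synthetic 88-gene stand-in
mk = fn.BUILTIN_MARKERS

ens = fn.sample_ensemble(grn, 50_000, seed=1)
print(f"mean steps {ens.mean_steps:.2f}, unique steady states {ens.n_states}")

ps = fn.phenotypic_score(grn, ens.states, mk, "PS")
em = fn.phenotypic_score(grn, ens.states, mk, "EM")
labels = fn.phenotype_extremes(ps, em)      # SM / PE / SE / PM / none
sm = ens.states[labels == "SM"]

assay = fn.reprogramming_assay(grn, np.repeat(sm, 10, axis=0), mk, seed=2)
print(assay.group_energy_summary().round(2))
```

prints

```
mean steps 54.49, unique steady states 877
              mean    std  count
productive                      
failed     -241.37  28.97   1450
productive -204.25  16.35     80
```

Reading: 50 000 random initial states relax to fixed points in ~54 flips on
average and concentrate on 877 distinct steady states. Clamping Pou5f1 ON
in somatic-mesenchymal starts reprograms a minority of trajectories
(ΔΦ_PS > 6, "productive"); those trajectories depart from start states with
markedly *higher* pseudo-energy (−204 vs −241), i.e. pre-existing
frustration is what lets the perturbation take hold — the central
observation this package is built to quantify.

A thin CLI wraps the same functions (`frustnet synth | relax | ensemble |
assay | screen | landscape | binarize`), each subcommand taking `--seed`
and an optional YAML `--config`.

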