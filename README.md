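# dimlight

Kinetic, spectral and phylogenetic analysis of dim-light visual
pigments.

Rod photoreceptors work at the absolute threshold of vision because rod
pigments almost never fire in the dark: the thermal isomerization rate
`k_th` of their 11-*cis* retinal chromophore is orders of magnitude
lower than in cone pigments. Deciding whether a candidate opsin (such
as pinopsin, the blue-sensitive pigment first found in the pineal organ
but also expressed in some retinas) can serve rod-like scotopic vision
therefore requires three quantitative ingredients, and this package
implements all three as a tested, simulation-backed pipeline:

1. **Chromophore thermal activity.** Under the two-step scheme
   R → R\* (rate `k_th`) → decay (rate `k_d`), the dark steady state
   gives

   ```
   k_th = (v_dark / v_light) · k_d
   ```

   `v_dark`, `v_light` and `k_d` are estimated from single-exponential
   fits to three assays (dark GTPγS uptake vs a locked-retinal control,
   flash-induced G-protein fluorescence with/without G protein, and
   retinal-release fluorescence), with SEMs over replicates combined by
   first-order error propagation:
   `ε_th = M_th · √((ε_dark/M_dark)² + (ε_light/M_light)² + (ε_d/M_d)²)`.
   Pigments are compared through relative rate constants with a
   two-tailed Student t test.

2. **Protein thermal stability.** λmax is fitted with the Govardovskii
   A1 absorbance template; residual pigment after 37 °C incubation is
   read from post-bleach difference spectra at 540 nm, normalized to
   t = 0, and fitted with first-order decay (half-life = ln 2 / k).

3. **Phylogenetic placement.** Per-site log-likelihoods of amino-acid
   alignments under JTT (+ discrete-gamma rates) are computed by
   Felsenstein pruning on every unrooted topology over up to 8 effective
   OTUs — 105 topologies for six OTUs, 15 when a four-taxon subtree such
   as `(((RH1,RH2),SWS2),SWS1)` is held fixed — with per-topology ML
   branch lengths, and compared by RELL-based KH, SH and AU
   (multiscale-bootstrap) tests.

A synthetic-data module (`dimlight.synth`) generates every input the
pipeline consumes from known ground truth — assay time courses,
template spectra with first-order pigment decay, alignments evolved on
a known tree, and exchangeable null site-likelihood matrices — so every
estimator is verifiable end to end without any external data.

## Worked example

Simulate a full study at one master seed, then run each analysis stage:

```
$ dimlight simulate --seed 7 --out demo
$ dimlight kth --timecourse demo/timecourse.csv --out demo/kth_results.csv
M_th = 3.83446e-05 s^-1, e_th = 6.88701e-06 s^-1

$ dimlight spectra --spectra demo/spectrum.csv --out demo
lambda_max = 476.9 nm; decay rate = 0.0003825 s^-1 (half-life 1812 s)
```

The ground truth recorded in `demo/truth.json` was
`k_th = 4e-05 s^-1`, `lambda_max = 477 nm` and decay half-life 1800 s:
the estimated thermal isomerization rate lands within one propagated
standard error, and the spectral estimates within 0.1 nm and 1 % —
this is the simulate → estimate → compare loop the test suite runs
hundreds of times.

Topology testing on a five-taxon alignment (15 possible unrooted
trees), generating the input through the library first:

```python
import dimlight as dl
jtt = dl.build_model("JTT")
tree = dl.read_newick("(((A:0.15,B:0.15):0.1,C:0.2):0.1,D:0.25,E:0.3);")
aln = dl.gen_alignment(tree, dl.EvolModel(jtt, dl.discrete_gamma(0.71, 4)),
                       200, seed=5)
dl.write_fasta(aln, "demo/five.fasta")
```

```
$ dimlight topotest --aln demo/five.fasta --alpha 0.71 --b 5000 --seed 1 --out demo/tt
15 topologies scored; ML topology id 14; 5 not rejected by the AU test at 5%
```

`demo/tt/topotest.csv` then ranks every topology by lnL with its ΔlnL,
RELL bootstrap proportion and AU/KH/SH p-values, e.g.

```
tree,topology_id,lnL,delta_lnL,BP,p_AU,p_KH,p_SH,...
1,14,-1479.61,0.00,0.823,0.950,1.000,1.000,...
2,12,-1483.24,3.62,0.091,0.198,0.288,0.475,...
```

— the ML tree and several near-ties survive at the 5 % level, exactly
the situation in which a gene-family branching order cannot be decided
from the data.

The same operations are available as a library
(`dimlight.estimate_k_th_from_bundle`, `dimlight.exhaustive_ml`,
`dimlight.summarize_tests`, ...); see `docs/methods.md` for the models,
defaults and numerical choices.

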