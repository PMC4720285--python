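# nflink — noise-filtering link prediction for complex networks

Many networked systems — protein–protein interaction maps, metabolic and
neural wiring diagrams, social and technological graphs — are observed
incompletely and imperfectly: some true links are missing and some recorded
links are spurious. **Link prediction** ranks the unlinked node pairs of an
observed graph by how likely they are to be true (missing or future) links.
`nflink` implements a spectral **noise-filtering (NF)** predictor together
with six classical similarity indices and the standard train/probe
evaluation protocol, for anyone benchmarking or applying link prediction to
undirected simple networks.

## The method

Treat each node's observed connections as its feature vector. Using rows of
**X = A + I** (not A alone) makes linked, topologically equivalent nodes —
same neighbourhoods — share identical features. For a feature column
**x**, the quadratic form of the normalized Laplacian
**L̃ = I − D<sup>−1/2</sup>AD<sup>−1/2</sup>**,

&nbsp;&nbsp;&nbsp;&nbsp;D(x) = xᵀL̃x = Σ<sub>i∼j</sub> (x<sub>i</sub>/√d<sub>i</sub> − x<sub>j</sub>/√d<sub>j</sub>)²,

measures how much the feature differs across linked nodes, with every node
weighted equally. Eigenvectors of L̃ with small eigenvalues vary slowly over
links ("low frequency"); those with large eigenvalues encode links between
dissimilar nodes, read as **noise**. Keeping the t lowest-frequency
eigenvectors V<sub>t</sub> = [v₁ … v<sub>t</sub>] gives filtered scores

&nbsp;&nbsp;&nbsp;&nbsp;Ŝ = V<sub>t</sub>V<sub>t</sub>ᵀ(A + I),&nbsp;&nbsp;&nbsp;
S\* = (Ŝ + Ŝᵀ)/2,

and every pair not linked in the training graph is ranked by its S\* entry.
The cutoff t is chosen by K-fold cross-validation on the training links and
then held fixed. Comparison indices: CN, AA, RA, PA (local), LP
(quasi-local, A² + εA³) and Katz ((I − βA)<sup>−1</sup> − I, global).
Accuracy is measured by **AUC** (probability a hidden probe link outscores a
random non-existent pair; ties count ½; 0.5 = chance) and
**precision@L** with L = |probe set|.

## Worked example

Hide 10% of the links of a 4-community planted-partition graph and rank
them back (`python examples/02_predict_missing_links.py`):

```
network: 100 nodes, 332 links (33 hidden as probes)

   method     AUC  prec@L
 NF (t=5)   0.887   0.030
       CN   0.744   0.061
       RA   0.744   0.030
     Katz   0.856   0.061
```

An AUC of 0.887 means a hidden link outranks a random non-existent pair
88.7% of the time; the spectral filter exploits the global block structure
that the purely local indices cannot see. The other examples walk through
the A + I feature construction on a five-node graph
(`01_five_node_walkthrough.py`), cross-validated selection of the cutoff t
(`03_select_cutoff.py`), the repeated-split benchmark protocol with
mean(sd) cells (`04_benchmark_protocol.py`), and robustness when the
observed network itself is randomly rewired (`05_noise_robustness.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
nflink generate --family planted_partition --n 100 --blocks 4 \
    --p-in 0.25 --p-out 0.01 --seed 5 --out net.edges
nflink stats net.edges
nflink select-t net.edges --k 5 --repeats 2 --seed 1 --out sel.json
nflink predict net.edges --method NF --t 5 --out scores.csv
nflink evaluate net.edges --methods NF,CN,RA --f 0.9 --runs 20 \
    --seed 17 --out bench.csv
```

Inputs are plain-text edge lists (two whitespace-separated labels per line;
`#`/`%` comments; duplicate links, self-loops and direction are stripped on
read). Every artifact gets a JSON sidecar with the resolved configuration,
so outputs are reproducible from their own metadata.

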