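# Methods

## The generative model

`qsimcells` simulates single-cell RNA-seq counts from a parameterized
quantum circuit in which each gene is one qubit. The pipeline is
deterministic given a configuration and a seed, and factors into four
stages.

**Circuit.** Every qubit starts in |0⟩ and receives Ry(θ) with
θ = activation·π, using the standard convention
Ry(θ) = [[cos(θ/2), −sin(θ/2)], [sin(θ/2), cos(θ/2)]], so a measured 1
("ON") has probability sin²(θ/2). The *activation proportion* p = θ/π and
the *ON-probability* sin²(θ/2) coincide only at 0, ½ and 1; both are exposed
(`GeneSpec.activation`, `GeneSpec.p_on`) and never conflated. Regulation and
communication are ordered lists of single-control CX gates; order matters
because CX gates on overlapping qubits do not commute. Two cell-type
registers are combined by a tensor product (CT1 on the low-order qubits),
and gates are addressed by global qubit index throughout. Intra-register
gate lists are applied after the tensor product rather than on the separate
registers: gates on disjoint qubit sets commute with the product, so the
final state is identical and the staging stays simple.

Since Ry on |0⟩ products and CX are real matrices, the state is a dense real
vector of 2ⁿ amplitudes, capped at n = 20. Amplitude index k encodes qubit i
in bit (k≫i)&1; logical bit strings print gene i at position i, and the
reversal of the raw little-endian printing order happens exactly once, in
`exact_distribution`.

**Oracle.** Because ψ₀ is a non-negative product state and every CX is a
basis permutation, the measurement distribution equals the push-forward of
independent Bernoulli(sin²(θᵢ/2)) bits through the circuit's XOR updates
(b_t ← b_t ⊕ b_c in gate order). `oracle.pushforward_distribution`
enumerates this exactly and independently of the statevector engine; the
test suite requires agreement to 1e−10 per outcome. This dual route is the
package's correctness anchor.

**Sampling.** Shots are one multinomial draw over the exact distribution —
statistically identical to per-shot measurement and much faster.
N_shots = m plays the role of the number of simulated observations.

**Counts.** Each bit string with count C(b) contributes C(b) observations.
In the default *paired* split every shot yields a CT1 cell and a CT2 cell
with off-type model genes structurally zeroed; this is what gives the two
cell types disjoint expression supports, at the cost that m shots produce
2m cells (m cells per type). The *joint* split (one untyped cell per shot)
is available when shots must equal cells. ON entries are replaced by
NB(r, p) draws with p = r/(μ+r) (masking, not multiplication — the draw
replaces the 1, so an ON gene can still yield a sampling zero with
probability pʳ); OFF entries remain exactly 0. Housekeeping genes are
appended as always-ON NB rows in every cell of both types.

## Defaults and what they represent

| parameter | default | meaning |
|---|---|---|
| activations | (0.2, 0.1, 0.4, 0.9, 0.8, 0.2, 0.3, 0.2, 0.7, 0.5) | demo register: 5 CT1 + 5 CT2 genes spanning low to near-saturating baselines |
| model-gene NB | μ=5, r=1 | low, strongly overdispersed expression typical of regulated genes |
| housekeeping block | 50 genes, μ=80, r=6 | high stable background; dominates the per-cell library (~4,000 counts) |
| shots m | 2,000 | 4,000 cells in paired mode; chosen as a realistic small-experiment scale at which |corr| ≈ 0.5 effects resolve clearly (null correlation SE ≈ 1/√4000 ≈ 0.016) |
| normalization target | 10,000 counts/cell | standard counts-per-10k |
| edge threshold | \|corr\| > 0.5, strict | ties excluded |
| permutations | 99 | minimum attainable p = 0.01 with the add-one estimator |

The two bundled experiments differ only in topology: `case1` applies the
inter-register cascade (3,5),(5,7),(7,0) at the final stage; `case2` the
single intra-CT1 link (2,1). The candidate ligand–receptor database holds
the two mechanistic pairs riding the cascade (g3→g5, g7→g0) and two false
controls among highly expressed but uncoupled genes (g8→g4, g9→g4).

## Network benchmark

Preprocessing follows the standard scanpy stack: per-cell normalization to
the target sum, log1p, per-gene z-score. All-zero cells are left as zeros
and flagged; zero-variance genes are excluded from correlation and reported.
Correlations (Pearson via `numpy.corrcoef`, Spearman via
`scipy.stats.spearmanr` with average ranks for ties) are computed over **all
cells pooled**: cross-type dependencies written by inter-register gates are
invisible within one type, where the partner gene is structurally zero.
Pooling also means every same-type gene pair shares its structural-zero
block, which produces baseline correlations between high-activation genes —
this is precisely the "spurious edge" phenomenon the benchmark is designed
to expose (e.g. the g3–g4 edge), and it places the strongest g8 correlation
essentially at the 0.5 cutoff. Truth comparison is undirected (correlation
has no directionality) against the programmed control–target list.

Two exact invariances are tested: Spearman is unchanged by the (monotone)
log1p step, and Pearson by the (affine) z-score step. The Spearman test uses
equal per-cell totals because with unequal libraries the normalized values
contain near-collisions that log1p can round into ties, perturbing ranks at
the 1e−4 level — an artifact of float64, not of the statistic.

## Communication score

CCC scoring deliberately avoids any external inference framework: with
ē_L the mean counts-per-10k (no log) of the ligand over sender-type cells
and ē_R likewise for the receptor over receiver-type cells, the score is the
Hill saturation S = ē_L·ē_R / (kh + ē_L·ē_R) ∈ [0, 1). The saturation
constant is data-adaptive: **kh = median of ē_L·ē_R over the candidate pair
database** (floored at machine epsilon), which places the typical candidate
pair at the Hill midpoint S = 0.5. A smaller constant (e.g. half the median)
pushes the strong pairs toward saturation and demonstrably compresses the
interacting-vs-control fold change of the cascade's first pair below the
designed ≥3× separation; the midpoint convention keeps every candidate on
the responsive part of the curve. When two conditions are contrasted, one
shared kh is computed from the candidate products pooled across both
matrices so the scores are on a single scale; fold change is
S_interacting / max(S_control, 1e−9), with an `unbounded` flag when the
control score is numerically zero. Significance per condition is a
cell-type label-permutation null with the add-one estimator
p = (1 + #{S_perm ≥ S_obs})/(1 + n_perm). Expression summaries use the
arithmetic mean, not a trimmed statistic — simpler, and sufficient for the
contrast readout the score exists for.

## What the generator does and does not emulate

The synthetic data reproduces: joint co-activation structure with explicit
causal direction and order, disjoint cell-type supports, overdispersed
counts with structural and sampling zeros, and a stable housekeeping
background. It does **not** model library-size variation between cells
(libraries fluctuate only through NB noise), dropout beyond the circuit
mask, batch effects, UMI resampling, or continuous expression gradients.
Passing benchmarks here therefore show how inference methods respond to
*dependency structure* under clean, well-normalized counts — not how they
cope with real-data nuisance variation.

## Numerical choices

- Statevector norm is validated to 1e−9 on construction; probabilities below
  1e−14 (floating-point residue of cos(π/2)) are dropped from exact
  distributions.
- The oracle refuses > 20 qubits (dense enumeration guard), matching the
  engine cap.
- Multinomial sampling iterates histogram keys in sorted order; NB draws are
  generated row-per-gene over all cells regardless of mask, so the random
  stream layout is independent of the measured pattern. Seeds for the shot,
  NB, housekeeping and permutation stages are spawned from the configured
  seed via `numpy.random.SeedSequence`.
- All JSON artifacts are written with sorted keys and no timestamps; reruns
  with identical config+seed are byte-identical (timings live in `run.log`,
  which is excluded from that contract).
- Edge retention uses strict inequality; a correlation exactly at the
  threshold is excluded.

## Known limitations

- Only single-control CX coupling is supported; multi-control gates would
  require no engine changes (any basis permutation works) but have no
  configuration surface.
- The dense engine is exact but exponential; 20 qubits ≈ 8 MiB of
  amplitudes is the practical ceiling.
- The communication score is a minimal mass-action model; its absolute
  values are convention-dependent (they move with the kh convention) and
  only fold changes across conditions are interpreted.
- With pooled-cell correlation and paired splitting, high-baseline genes of
  different types acquire structural anti-correlations near the edge
  threshold; conclusions about "isolated" genes are therefore stated with a
  ±0.05 band around the cutoff at the default scale.
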