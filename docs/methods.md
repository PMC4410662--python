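# Methods

## Model

The anisotropic network model treats a structure as N point nodes joined by
identical Hookean springs. The potential is

    E = sum over contacts (i,j) of (gamma/2) * (|R_i - R_j| - d0_ij)^2,

where d0_ij is the separation in the input structure, so the input is the
energy minimum by construction. The Hessian at that minimum decomposes into
3x3 super-elements: H[i,j] = -(gamma/d0^2) r_ij r_ij^T for each contact
(r_ij the equilibrium separation vector) and diagonal blocks that close each
super-row to zero. This guarantees translation invariance exactly; rotation
invariance (three more zero modes) follows from the pairwise-distance form of
E. The harmonic ensemble's displacement covariance is the Moore–Penrose
pseudo-inverse of H (times k_B T / gamma), computed in practice from the m
lowest nonzero eigenpairs: cov_ij = sum_k u_k,i u_k,j^T / lambda_k. All
fluctuation observables (MSF, B-factors, ADP tensors, correlation and
distance-fluctuation maps) are linear functionals of these blocks.

Assumptions worth stating: single static conformation (first model of a
multi-model file), unit masses, a uniform spring constant, and no solvent or
crystal environment. The model predicts directions and relative amplitudes of
collective motions, not absolute magnitudes or time scales.

## Coarse-graining and cutoffs

- Amino acids contribute one node per scheme atom present (default Calpha).
- Standard nucleotides (A, C, G, U, T, DA, DC, DG, DT, DU) contribute one
  node per scheme atom present, default P, C4' and C2 — backbone phosphate,
  sugar and base positions. A 5'-terminal nucleotide without a phosphate
  simply contributes fewer nodes (warning logged), mirroring how real PDB
  files must be handled.
- Ligands: every non-hydrogen HETATM atom becomes a node unless its residue
  is excluded (waters HOH/WAT/DOD by default). One node per heavy atom keeps
  the mapping parameter-free; a per-ligand centroid variant was considered
  and rejected as lossy for multi-ring ligands.
- Hydrogens never become nodes; alternate locations are resolved to the
  highest-occupancy conformer (ties: first in file) at parse time.

Each node carries an interaction range t_i looked up by type key
("PRO:CA", "NUC:P", "LIG:C1"), then by bare atom name, then defaulting to
cutoff/2 (cutoff default 15 Angstrom — the standard compromise between
B-factor agreement at larger cutoffs and ADP realism at smaller ones). A
spring joins i and j iff d0 <= t_i + t_j, boundary inclusive; inclusivity
makes the empty-table case agree exactly with a direct d0 <= r_c rule even at
the boundary. Contact enumeration uses a KD-tree pruned at 2*max(t) followed
by the exact pairwise test, so it is identical to all-pairs enumeration (a
tested invariant). Node pairs closer than 1e-6 Angstrom are an error, not a
merged node: coincident nodes make the Hessian block ill-defined.

gamma = 1 uniformly and k_B T / gamma = 1: no published value exists for
these toy-model constants, and every output is therefore in relative units,
with a closed-form least-squares scale s = <B_th, B_exp>/<B_th, B_th>
(optionally affine) provided for comparison with experimental B columns.

## Eigensolvers

Two routes, contractually equivalent (tested to 1e-8 relative on 30–200-node
systems):

- dense: `scipy.linalg.eigh` on the full matrix, used for 3N <= 1500;
- subset: ARPACK shift-invert (`scipy.sparse.linalg.eigsh`) about
  sigma = -max(1e-6 * lambda_max, 1e-12). The small negative shift keeps the
  factorized matrix H - sigma*I positive definite even though H itself is
  singular, and the eigenvalues nearest sigma are exactly the smallest ones.

Eigenvalues below max(1e-8 * lambda_max, 1e-10) are classified as rigid-body
modes and skipped; a connected 3-D network must yield exactly six, and any
other count raises a disconnected/degenerate-network error unless explicitly
overridden (the two-node analytic system, with five rigid-body modes, is the
canonical override case). The default number of retained nonzero modes is 20.
Eigenvector sign is fixed by making the largest-magnitude component positive,
for reproducible output files; within degenerate eigenvalue clusters only the
spanned subspace is well-defined, so cross-solver comparisons use subspace
overlaps rather than per-vector identity.

Externally computed mode vectors can replace the solver: a matrix with 3N
rows (vectors only, eigenvalues set to 1) or 3N+1 rows (leading eigenvalue
row) is accepted, columns are normalized, and non-orthogonality only warns,
since external methods (e.g. trajectory PCA) need not produce orthogonal
vectors in this basis. Any other row count is rejected with the expected 3N
quoted.

## Observables and output conventions

- MSF and B: msf_i = sum_k |u_k,i|^2 / lambda_k, B = (8 pi^2 / 3) msf.
- ADPs: U_i = sum_k u_k,i u_k,i^T / lambda_k; trace(U_i) = msf_i identically.
  ANISOU integers are round(U_ij * scale * 1e4) per the PDB convention, so a
  write/read round trip is exact to 1e-4 * scale.
- Correlation: C_ij = tr(cov_ij) / sqrt(msf_i msf_j), in [-1, 1].
- Distance fluctuations: D_ij = msf_i + msf_j - 2 tr(cov_ij), the
  mean-square relative displacement — the standard elastic-network proxy for
  a "distance fluctuation" map (small D = rigidly coupled pair).
- Animations sweep one full sine period; the amplitude parameter is the
  maximum per-node displacement in Angstrom (not the thermal amplitude
  1/sqrt(lambda)), chosen so different modes are visually comparable. Frame 0
  is the input structure bit-exactly.
- CLI matrices are printed at %.6e and TSV profiles at %.4f, fixed so that a
  rerun with the same input and flags is byte-identical.

## Synthetic fixtures

The fixture generators produce deterministic toy PDB files: compact
self-avoiding Calpha walks (a globular chain; an extended near-collinear
chain would have bending modes soft enough to blur the rigid-body gap),
ideal helices, uniform random clouds whose box scales as 5.5 * N^(1/3) to
keep density (and hence connectivity at the 15 Angstrom cutoff) constant, and
mixed protein/DNA/ligand complexes with a phosphate-less 5'-terminal
nucleotide and a water, exercising the coarse-graining edge cases. The rigid
perturbation helper draws its rotation from the 24 proper lattice rotations
and snaps translations to the 1e-3 Angstrom grid: these motions commute with
the PDB format's three-decimal coordinate columns, so spectrum-invariance
checks through file round trips are exact rather than quantization-limited;
generic (non-lattice) rotations are exercised in-memory.

What the fixtures do not emulate: realistic polymer stereochemistry,
sequence-dependent packing, experimental B-factor profiles (the B column is
a smooth synthetic curve, so fitted Pearson r on fixtures is not a
prediction-quality statistic), crystal contacts, or structure-file pathology
beyond missing atoms and altlocs. Passing tests demonstrate the mechanics
and invariants of the method, not B-factor prediction accuracy on real
crystal structures.

## Numerical choices and limitations

- Zero-mode tolerance 1e-8 relative with a 1e-10 absolute floor; problem
  sizes in tests and the acceptance script (N up to 200, full decompositions
  up to N = 40) keep every check well inside that separation.
- Finite-difference Hessian oracle: central differences at h = 1e-4 on the
  harmonic energy, agreeing with the analytic assembly to ~1e-8.
- The dense/subset threshold (3N = 1500) is a performance heuristic only.
- Multi-model NMR files use model 1 only; no symmetry expansion, no mmCIF,
  no mass weighting, no distance-dependent spring constants, no Gaussian
  (isotropic) network variant.
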