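# coevodock

Coevolution-guided interface inference and coarse-grained docking for
multi-protein complexes, built around the workflow used to study how the
NEDD1 WD40 β-propeller binds inside the V-junction of the eight-subunit
Augmin complex: paired alignments of interacting protein families are fed to
mean-field direct coupling analysis (DCA), the resulting residue–residue
couplings are filtered by statistical enrichment and solvent accessibility,
and the surviving pairs restrain a structure-based (Gō-model) docking
simulation.  Crosslinking mass-spectrometry residue pairs provide an
orthogonal distance-based validation channel.

The package is aimed at structural bioinformaticians who have family
alignments (or want to simulate them), coordinate models, and residue-pair
crosslink tables, and who want a tested, scriptable version of the whole
chain — including a synthetic-data module so every stage can be exercised
and benchmarked without any external downloads.

## The statistics at the core

Given a paired alignment of families A and B (rows concatenated per species
by progressive paralog matching), mean-field DCA proceeds as:

1. **Reweighting** — row weight `w_m = 1/|{m' : identity(m, m') ≥ 0.8}|`,
   effective depth `M_eff = Σ w_m`.
2. **Regularized frequencies** — `f_i(a) = (λ/q + Σ_m w_m 𝟙[x_mi = a]) /
   (λ + M_eff)` with pseudocount `λ = M_eff` and `q = 21` states
   (20 amino acids + gap), pair frequencies analogous with `λ/q²`.
3. **Couplings** — `e_ij(a,b) = −(C⁻¹)` over the connected correlations
   `C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)` restricted to `q−1` states
   (gap is the reference).
4. **Direct Information** — for each pair, the two-site distribution
   `P_dir(a,b) ∝ exp(e_ij(a,b)) h̃_i(a) h̃_j(b)` with fields fixed-point
   iterated until both marginals match `f_i, f_j`; then
   `DI_ij = Σ_ab P_dir(a,b) ln [P_dir(a,b) / (f_i(a) f_j(b))]` (nats).

Inter-domain pairs ranked by DI are scored against a reference structure
with an exact right-tailed hypergeometric test (`P(X ≥ k)` for `k` true
contacts among the top `n` of `N` inter-domain pairs containing `K`
contacts), retained at `p ≤ 0.2`, filtered by combined per-residue
Shrake–Rupley SASA `> 100 Å²`, and the top 10 survivors become attractive
12-10 wells (`ε[5(σ/r)¹² − 6(σ/r)¹⁰]`) in a Cα structure-based model
integrated with BAOAB Langevin dynamics.  Crosslink satisfaction uses the
standard BS3 criterion, Cα–Cα `< 35 Å`, with multi-copy assemblies resolved
to the distance-minimizing chain assignment.

## Worked example

Generate a paired alignment with three planted inter-domain couplings of
strength 2.0, concatenate by species, and rank DI pairs:

```bash
coevodock synth msa --length-a 10 --length-b 10 --n-sequences 300 \
    --n-planted 3 --strength 2.0 --seed 1 --out-a famA.fasta --out-b famB.fasta
coevodock msa concat famA.fasta famB.fasta -o paired.fasta
coevodock dca run paired.fasta --boundary 10 --top 5 -o di.tsv
```

which prints `paired 300 rows; boundary at column 10` and then
`wrote 5 DI pairs (M_eff = 300.0)`, with `di.tsv` containing:

```
rank  i  j   domain_i  domain_j  DI
1     5  8   A         B         0.5690398300819679
2     4  10  A         B         0.5380240025866718
3     8  2   A         B         0.4457039455493093
4     8  7   A         B         0.2902705743473337
5     1  6   A         B         0.26383953938741633
```

The three top-ranked pairs (DI ≈ 0.45–0.57 nats, well above the ≈0.03-nat
ceiling measured on coupling-free alignments of this depth) are exactly the
three planted couplings for this seed; `i` and `j` are 1-based positions
inside domains A and B.  Mapping a synthetic 5-true/5-decoy crosslink table
onto the matching toy complex:

```bash
coevodock synth complex --chains 20,20 --interface "A:5-B:5,A:10-B:10" -o toy.pdb
coevodock synth xlinks --pdb toy.pdb --n-true 5 --n-decoy 5 --seed 2 -o xl.tsv
coevodock xlink map xl.tsv toy.pdb --config chains.toml -o mapped.tsv
```

where `chains.toml` names each protein's chain copies and numbering offset
(author residue number = construct position + offset):

```toml
[A]
chains = ["A"]
offset = 0
[B]
chains = ["B"]
offset = 0
```

reports `5 of 10 mapped records < 35.0 A (fraction 0.500)` — the five
distance-consistent records satisfy the crosslinker bound, the five decoys
do not.  A short restrained docking run
(`coevodock dock run --steps 20000 --seed 1`) prints

```json
{"contact_fraction": 0.8, "ligand_rmsd": 15.88, "final_com_distance": 7.76}
```

showing the ligand chain already forming 8 of the 10 restrained interface
contacts after 20k steps (full benchmark runs use 500k).

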