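# rfsim

Reaction-similarity scoring and enzyme suggestion for biochemical
reactions — including **unbalanced** ones, where cofactors or leaving
groups are missing from the equation.

Metabolic engineers running retrosynthesis tools end up with lists of
reactions that need enzymes. When a reaction (or a novel/orphan reaction)
is not in an enzyme database, the standard move is to find *similar*
annotated reactions and borrow their enzymes, hoping for promiscuity or an
engineerable active site. `rfsim` ranks a reaction database against a
query with two scores:

* **sim_2018** — whole-compound similarity: counted Morgan fingerprints
  (radius ≤ 8, ring membership excluded), counted Tanimoto
  T(A,B) = Σₖ min(Aₖ,Bₖ) / Σₖ max(Aₖ,Bₖ), greedy query↔database compound
  pairing per side, and the mean of the substrate and product side means.
* **sim_RF** — reacting-fragment similarity: atom–atom mapping locates the
  reacting atoms; fragments containing them are weighted by a reverse
  sigmoid f(x) = 1/(1 + e^{k(x−i)}) of their distance-to-centre x
  (defaults k = 0.5, i = 5), normalised to Σ s_norm = 1 per compound; each
  paired compound contributes the containment Σ s_norm over query RF keys
  found in the database compound, and sides combine as
  sim_RF = √(S̄ · P̄).

Whole-compound similarity is easily seduced by large shared scaffolds or
cofactors attached to unrelated chemistry; the RF score focuses on what
actually changes, and its asymmetric containment keeps it applicable when
the query is unbalanced. Reactions that cannot be mapped (wildcard `*`
SMILES, mapper failure) remain searchable by sim_2018 with the RF column
reported `NA`.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Build a database from the shipped planted fixture and query it with an
ω-amide fatty-alcohol oxidation it contains:

```bash
python - <<'PY'
from rfsim.fixtures import FixtureSpec, write_planted_tables
write_planted_tables(FixtureSpec(seed=1), "scratch/demo")
PY
rfsim build-db --compounds scratch/demo/compounds.tsv \
               --reactions scratch/demo/reactions.tsv \
               --enzymes scratch/demo/enzymes.csv --out scratch/demo/db.json
# first query from the generated query file (a pre-mapped alcohol oxidation)
Q=$(awk -F'\t' 'NR==2{print $2}' scratch/demo/queries.tsv)
rfsim query --db scratch/demo/db.json --targets 6 --score-by sim_rf --smiles "$Q"
```

Output:

```
reaction_id  sim_2018             sim_RF              EC       enzyme_id  organism           is_identical
R_A1         1.0                  0.9999999999999996  1.1.1.1  ENZ_A1a    Escherichia coli   True
R_A1         1.0                  0.9999999999999996  1.1.1.1  ENZ_A1b    Bacillus subtilis  True
R_A2         0.36486486486486486  0.9183105201288212  1.1.1.2  ENZ_A2a    Escherichia coli   False
R_A2         0.36486486486486486  0.9183105201288212  1.1.1.2  ENZ_A2b    Bacillus subtilis  False
R_A3         0.3357664233576642   0.8902084153401224  1.1.1.3  ENZ_A3a    Escherichia coli   False
R_A3         0.3357664233576642   0.8902084153401224  1.1.1.3  ENZ_A3b    Bacillus subtilis  False
```

The query's own reaction ranks first with both scores 1 and is flagged
identical. The best *non-identical* RF suggestions are the same alcohol
oxidation on distally-modified scaffolds (EC 1.1.1.x, 3 shared digits), an
enzyme family a bench scientist could plausibly recruit — whereas ranking
the same rows by `sim_2018` instead puts the decoy `R_B1` (an amide
hydrolysis of the *same* substrate, EC 3.5.1.1, 0 shared digits) on top of
the non-identical list. `rfsim evaluate` and `rfsim sweep` run the
EC-digit accuracy protocol and the (k, i) parameter grid over a query set.

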