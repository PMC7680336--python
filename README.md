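# phylosym

Rate-matrix algebras generated by rooted trees.

Given a rooted tree whose leaves are labelled by states (taxa) and whose
non-leaf vertices carry symbolic rate labels, `phylosym` builds the basis of
symmetric, zero-row-sum integer rate matrices in which the off-diagonal
entry for a state pair is 1 exactly when that pair's most recent common
ancestor carries the given rate.  On top of that construction it provides:

- **Tree structure** (`phylosym.treecore`): Newick I/O (internal labels are
  rate names), cluster sets / laminar hierarchies and their inverse tree
  reconstruction, MRCA queries, vertex relations, subtree sizes.
- **MRCA basis** (`phylosym.mrca_basis`): the partition classes, the basis
  matrices, and the all-ones-style sum matrices for the full tree and for
  subtrees (exact integer arithmetic throughout).
- **Graph view** (`phylosym.tigs`): per-rate MRCA graphs (complete
  multipartite plus isolated vertices), a structural validator for
  tree-induced graph sets, the bijection with hierarchies, and Laplacians
  satisfying `Q = -L(G)`.
- **Algebra** (`phylosym.algebra`): closed-form products and squares,
  structure constants, exact span-membership tests exploiting disjoint
  off-diagonal supports, a closure decision with residual witnesses, and
  numeric instantiation `Q` / `I + Q` with exact determinants for rational
  rates.
- **Constraints** (`phylosym.constraints`): merged bases for rate-equality
  classes, the five-way positional classification of a merged vertex pair
  (only parent-child and equal-size siblings preserve closure), a
  connected-identification sufficient condition, a combined decision
  procedure with rationale, and model parameter counts.
- **Tooling** (`phylosym.generate`, `phylosym.fixtures`, `phylosym.cli`):
  a seeded random-tree generator, built-in `fig1` / `k2p` fixtures, a
  symbolic matrix-pattern export, and a CLI.

## CLI

All subcommands accept `--tree` as a Newick file, a literal Newick string,
or a fixture name (`fig1`, `k2p`); output goes to stdout or `--out`.

```sh
phylosym basis --tree fig1                      # TSV basis matrices
phylosym basis --tree '((a,b)x,c)r;' --format json
phylosym tigs --tree fig1                       # graph-set manifest + validity
phylosym products --tree fig1                   # structure constants
phylosym closure --tree fig1 --merge beta=gamma # algebra decision + witness
phylosym check-pair --tree fig1 --pair beta,gamma
phylosym random-tree --leaves 8 --seed 3 --max-children 4
phylosym export --tree k2p                      # symbolic matrix pattern
```

The `k2p` fixture is the four-state DNA tree `((A,G)b,(C,T)c)a;` with the
two cherry rates merged; its closure report is a closed two-parameter
algebra with the familiar transition/transversion pattern.

## Library example

```python
import phylosym as ps

tree = ps.parse_newick("((1,2)beta,(3,(4,5)delta)gamma)alpha;")
b = ps.basis(tree)                      # rate -> BasisMatrix
ps.product_coeffs(tree, "alpha", "gamma")   # {'gamma': -2}
ps.closure_check(b).closed                  # True

classes = ps.RateClasses.parse_merge_spec(tree, ["beta=gamma"])
ps.decide_algebra(tree, classes).closed     # False (unequal-size siblings)
```

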