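"""Independent reference implementations used only to cross-check the package.

These deliberately re-derive results from first principles (direct parsing,
explicit loops) without calling into the package's own code paths.
"""

from __future__ import annotations

from rdkit import Chem


def bond_diff_reacting_atoms(reaction_smiles: str):
    """Per-atom environment diff of a pre-mapped reaction.

    For every atom, build (element, formal charge, total H count, sorted
    multiset of (neighbour map number, bond order) over mapped neighbours).
    An atom is reacting iff it lacks a mapped partner on the other side or
    its descriptor differs from its partner's. Returns one set of 0-based
    atom indices per compound instance per side.
    """
    left, _, right = reaction_smiles.partition(">>")
    sides = []
    for part in (left, right):
        mols = [Chem.MolFromSmiles(s) for s in part.split(".")]
        assert all(m is not None for m in mols)
        sides.append(mols)

    def describe(mols):
        desc = {}   # map number -> descriptor
        where = {}  # map number -> (instance, atom index)
        unmapped = []  # (instance, atom index)
        for i, mol in enumerate(mols):
            for atom in mol.GetAtoms():
                m = atom.GetAtomMapNum()
                if not m:
                    unmapped.append((i, atom.GetIdx()))
                    continue
                neigh = sorted(
                    (b.GetOtherAtom(atom).GetAtomMapNum(), b.GetBondTypeAsDouble())
                    for b in atom.GetBonds()
                    if b.GetOtherAtom(atom).GetAtomMapNum()
                )
                desc[m] = (atom.GetSymbol(), atom.GetFormalCharge(),
                           atom.GetTotalNumHs(), tuple(neigh))
                where[m] = (i, atom.GetIdx())
        return desc, where, unmapped

    (dl, wl, ul), (dr, wr, ur) = describe(sides[0]), describe(sides[1])
    out_l = [set() for _ in sides[0]]
    out_r = [set() for _ in sides[1]]
    for i, a in ul:
        out_l[i].add(a)
    for i, a in ur:
        out_r[i].add(a)
    for m, d in dl.items():
        if m not in dr:
            out_l[wl[m][0]].add(wl[m][1])
        elif d != dr[m]:
            out_l[wl[m][0]].add(wl[m][1])
            out_r[wr[m][0]].add(wr[m][1])
    for m in dr:
        if m not in dl:
            out_r[wr[m][0]].add(wr[m][1])
    return [frozenset(s) for s in out_l], [frozenset(s) for s in out_r]


def greedy_pairing_trace(matrix):
    """Literal global-greedy trace on a score matrix (rows: query, cols: db).

    Repeatedly pick the largest remaining cell (ties: smallest row, then
    smallest column), fix it, delete its row and column.
    """
    n_q = len(matrix)
    n_d = len(matrix[0]) if n_q else 0
    rows = list(range(n_q))
    cols = list(range(n_d))
    pairs = []
    while rows and cols:
        best = None
        for q in rows:
            for d in cols:
                cell = (matrix[q][d], -q, -d)
                if best is None or cell > best:
                    best = cell
        s, nq, nd = best
        q, d = -nq, -nd
        pairs.append((q, d, s))
        rows.remove(q)
        cols.remove(d)
    return pairs
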