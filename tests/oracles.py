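"""Independent reference implementations used as test oracles.

These are deliberately written from the model equations directly (explicit
per-species arithmetic, no reuse of the package's term machinery) so they can
catch bookkeeping errors in the rule-based generator.
"""

from itertools import combinations

import numpy as np

AVO_NM_ML = 6.02214076e11  # molecules per mL per nM
EPS = 1e-12


# species layout of the minimal two-cell model (one T pool carrying CD3, one
# tumor pool carrying CD38, one pairing), written out by hand
MINIMAL_SPECIES = [
    "drug",
    "cell.T",
    "cell.MM",
    "syn.MM:CD38|T:CD3",
    "rec.CD3.free@cell.T",
    "rec.CD3.bound@cell.T",
    "rec.CD38.free@cell.MM",
    "rec.CD38.bound@cell.MM",
    "rec.CD38.free@syn.MM:CD38|T:CD3#MM",
    "rec.CD38.bound@syn.MM:CD38|T:CD3#MM",
    "rec.CD3.free@syn.MM:CD38|T:CD3#T",
    "rec.CD3.bound@syn.MM:CD38|T:CD3#T",
]

MINIMAL_LINEAGES = ["cells.CD8-T", "cells.tumor", "rec.CD3.CD8-T",
                    "rec.CD38.tumor", "drug"]


def minimal_rhs(x, p):
    """Hand-coded derivative of the minimal model's 22-dim state
    (12 species + synthesis/degradation accumulators for 5 lineages).

    ``p`` maps parameter names to values.
    """
    (DRUG, T, MM, SYN, F3T, B3T, F38M, B38M,
     F38S, B38S, F3S, B3S) = [max(float(v), 0.0) for v in x[:12]]
    d = np.zeros(22)
    V = p["volume"]
    b = p["bridges_per_synapse"]
    c = p["collision.MM|T"]
    kbind3 = p["kon.CD3"] / (AVO_NM_ML * V)
    kbind38 = p["kon.CD38"] / (AVO_NM_ML * V)

    def add(i, v):
        d[i] += v

    # drug binding / unbinding on all four receptor contexts
    for free_i, bound_i, kon_c, koff in (
        (4, 5, kbind3, p["koff.CD3"]),       # CD3 on free T
        (10, 11, kbind3, p["koff.CD3"]),     # CD3 on synapsed T
        (6, 7, kbind38, p["koff.CD38"]),     # CD38 on free MM
        (8, 9, kbind38, p["koff.CD38"]),     # CD38 on synapsed MM
    ):
        on = kon_c * DRUG * max(x[free_i], 0.0)
        off = koff * max(x[bound_i], 0.0)
        add(free_i, off - on)
        add(bound_i, on - off)
        add(0, off - on)

    # synapse formation; two directions by which arm is pre-bound
    f1 = c * p["kon.CD3"] * B38M * F3T / (AVO_NM_ML * V * b)   # CD3 bond forms
    f2 = c * p["kon.CD38"] * B3T * F38M / (AVO_NM_ML * V * b)  # CD38 bond forms
    f = f1 + f2
    add(1, -f)
    add(2, -f)
    add(3, +f)
    add(11, -b * f2)  # b pre-bound CD3 sequestered into bridges
    add(10, -b * f1)  # b free CD3 consumed by the newly formed bond
    add(9, -b * f1)   # b pre-bound CD38 sequestered
    add(8, -b * f2)   # b free CD38 consumed
    for pool_i, syn_i, pool_n in ((4, 10, T), (5, 11, T), (6, 8, MM), (7, 9, MM)):
        tr = f * max(x[pool_i], 0.0) / (pool_n + EPS)
        add(pool_i, -tr)
        add(syn_i, +tr)

    # dissociation; the bond that breaks determines where the drug stays
    g3 = p["koff.CD3"] * SYN    # CD3 bond breaks: drug stays bound on CD38/MM
    g38 = p["koff.CD38"] * SYN  # CD38 bond breaks: drug stays bound on CD3/T
    add(3, -(g3 + g38))
    add(1, +(g3 + g38))
    add(2, +(g3 + g38))
    add(7, +b * g3)   # bound CD38 back on the free-MM pool
    add(4, +b * g3)   # free CD3 back on the free-T pool
    add(5, +b * g38)
    add(6, +b * g38)
    for pool_i, syn_i in ((4, 10), (5, 11), (6, 8), (7, 9)):
        tr = (g3 + g38) / max(SYN, EPS) * max(x[syn_i], 0.0) if SYN > 0 else 0.0
        # first-order in the synapse-context species:
        tr = (p["koff.CD3"] + p["koff.CD38"]) * max(x[syn_i], 0.0)
        add(syn_i, -tr)
        add(pool_i, +tr)

    # lifecycle (free pools only); newborn cells carry fresh free receptors
    kpT, kdT = p["k_prolif.T"], p["k_deg.T"]
    kpM, kdM = p["k_prolif.MM"], p["k_deg.MM"]
    add(1, (kpT - kdT) * T)
    add(2, (kpM - kdM) * MM)
    add(4, kpT * T * p["R.CD3.T"] - kdT * F3T)
    add(5, -kdT * B3T)
    add(6, kpM * MM * p["R.CD38.MM"] - kdM * F38M)
    add(7, -kdM * B38M)

    # flux accumulators: synth, deg per lineage in MINIMAL_LINEAGES order
    d[12] = kpT * T
    d[13] = kdT * T
    d[14] = kpM * MM
    d[15] = kdM * MM
    d[16] = kpT * T * p["R.CD3.T"]
    d[17] = kdT * (F3T + B3T)
    d[18] = kpM * MM * p["R.CD38.MM"]
    d[19] = kdM * (F38M + B38M)
    d[20] = 0.0
    d[21] = kdT * B3T + kdM * B38M
    return d


def brute_force_pairings(cells, receptor_arms):
    """All admissible pairings by exhaustive search over distinct cell pairs
    and receptor pairs under the distinct-arm constraint.

    ``cells`` maps cell name -> list of receptor names; ``receptor_arms``
    maps receptor name -> arm name.  Returns a set of canonically ordered
    (cell_a, receptor_a, cell_b, receptor_b) tuples.
    """
    out = set()
    for ca, cb in combinations(sorted(cells), 2):
        for ra in cells[ca]:
            for rb in cells[cb]:
                if receptor_arms[ra] != receptor_arms[rb]:
                    pair = tuple(sorted([(ca, ra), (cb, rb)]))
                    out.add((pair[0][0], pair[0][1], pair[1][0], pair[1][1]))
    return out


def brute_force_prcc(X, y):
    """Partial rank correlation via explicit double regression residuals.

    For each column j of X: rank-transform everything, regress rank(x_j) and
    rank(y) on the ranks of the remaining columns (with intercept), and
    correlate the two residual vectors.
    """
    from scipy.stats import rankdata, pearsonr

    X = np.asarray(X, dtype=float)
    n, k = X.shape
    Xr = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    yr = rankdata(np.asarray(y, dtype=float))
    out = np.zeros(k)
    for j in range(k):
        others = np.column_stack(
            [np.ones(n)] + [Xr[:, m] for m in range(k) if m != j])
        beta_x, *_ = np.linalg.lstsq(others, Xr[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, yr, rcond=None)
        rx = Xr[:, j] - others @ beta_x
        ry = yr - others @ beta_y
        out[j] = pearsonr(rx, ry)[0]
    return out
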