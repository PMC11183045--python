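"""Connection specificity index (CSI) and regulon-module detection.

The CSI sharpens a Pearson-correlation network: two regulons are
specifically connected when few other regulons correlate with either of
them more strongly than they correlate with each other.  Hierarchical
clustering of CSI rows (Euclidean distance) then yields regulon modules,
renamed M1..Mk by decreasing size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


def pcc_matrix(ras: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between regulon activity columns.

    Constant columns have undefined correlation; their entries are stored
    as 0 (diagonal stays 1) with a warning.
    """
    if ras.shape[0] < 3:
        raise ValueError("need at least 3 units to correlate")
    x = ras.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant regulon columns; "
                      "correlations stored as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ras.columns, columns=ras.columns)


def csi_matrix(pcc: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Connection specificity index from a PCC matrix.

    ``CSI(A, B)`` is the fraction of the other N-2 regulons C with
    ``PCC(A,C) <= PCC(A,B)`` and ``PCC(B,C) <= PCC(A,B)`` (strict ``<``
    when ``strict=True``).  The diagonal is 1 and values lie on the grid
    {0, 1/(N-2), ..., 1}.
    """
    p = pcc.to_numpy(dtype=float)
    n = p.shape[0]
    if p.shape[0] != p.shape[1] or not np.allclose(p, p.T, atol=1e-12):
        raise ValueError("PCC matrix must be square and symmetric")
    if n < 3:
        raise ValueError("CSI needs at least 3 regulons")
    out = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            thr = p[a, b]
            if strict:
                ok = (p[a] < thr) & (p[b] < thr)
            else:
                ok = (p[a] <= thr) & (p[b] <= thr)
            ok[a] = ok[b] = False
            out[a, b] = out[b, a] = ok.sum() / (n - 2)
    return pd.DataFrame(out, index=pcc.index, columns=pcc.columns)


def cluster_modules(csi: pd.DataFrame, n_modules: int = 8,
                    method: str = "average") -> pd.Series:
    """Cut an agglomerative tree over CSI rows into k modules.

    Distances are Euclidean between CSI row vectors; modules are renamed
    M1..Mk in decreasing size order (ties by first member position).
    Returns a regulon -> module-name Series.
    """
    n = csi.shape[0]
    if n_modules > n:
        raise ValueError(f"k={n_modules} exceeds {n} regulons")
    z = linkage(pdist(csi.to_numpy(), metric="euclidean"), method=method)
    raw = fcluster(z, t=n_modules, criterion="maxclust")
    order = sorted(set(raw), key=lambda c: (-(raw == c).sum(),
                                            int(np.flatnonzero(raw == c)[0])))
    remap = {c: f"M{i + 1}" for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=csi.index, name="module")


def module_activity(ras: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Units x modules mean activity over member regulons."""
    missing = set(ras.columns) - set(modules.index)
    if missing:
        raise ValueError(f"modules missing assignments for {sorted(missing)[:5]}")
    cols = {}
    for m in sorted(modules.unique(), key=lambda s: (len(s), s)):
        members = modules.index[modules == m]
        cols[m] = ras[members].mean(axis=1)
    return pd.DataFrame(cols, index=ras.index)
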