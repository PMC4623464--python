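"""Independent reference computations used only by the tests.

These deliberately avoid the code paths of the package: the ANOVA oracle
works from marginal cell means with textbook balanced-design formulas, and
the nonparametric oracles exhaustively enumerate the permutation
distributions.
"""

from itertools import combinations, product

import numpy as np
from scipy import stats


def wilcoxon_exact_p(d) -> float:
    """Two-sided signed-rank p by full enumeration of the 2^n sign vectors."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided U-test p by enumeration of all group labelings."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    combined = np.concatenate([a, b])
    n1, N = len(a), len(combined)
    ranks = stats.rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in combinations(range(N), n1)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def mixed_anova_cell_means(df, subject="subject", group="group",
                           w1="w1", w2="w2", dv="dv"):
    """Balanced three-way mixed ANOVA (two within, one between factor) from
    marginal means; requires equal group sizes. Returns {effect: (ss_effect,
    ss_error, df, df_error)} keyed like the package's effect names."""
    subs = sorted(df[subject].unique())
    groups = df.groupby(subject)[group].first()
    G = sorted(groups.unique())
    J = sorted(df[w1].unique())
    K = sorted(df[w2].unique())
    Y = np.array([
        [[df[(df[subject] == s) & (df[w1] == j) & (df[w2] == k)][dv].iloc[0]
          for k in K] for j in J]
        for s in subs
    ])
    g_of = np.array([G.index(groups[s]) for s in subs])
    S, nJ, nK = Y.shape
    nG = len(G)
    n = S // nG
    assert all((g_of == gi).sum() == n for gi in range(nG)), "oracle needs equal groups"

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_g = np.array([m_s[g_of == gi].mean() for gi in range(nG)])
    m_j = Y.mean(axis=(0, 2))
    m_k = Y.mean(axis=(0, 1))
    m_gj = np.array([[Y[g_of == gi][:, j, :].mean() for j in range(nJ)]
                     for gi in range(nG)])
    m_gk = np.array([[Y[g_of == gi][:, :, k].mean() for k in range(nK)]
                     for gi in range(nG)])
    m_jk = Y.mean(axis=0)
    m_gjk = np.array([[[Y[g_of == gi][:, j, k].mean() for k in range(nK)]
                       for j in range(nJ)] for gi in range(nG)])
    m_sj = Y.mean(axis=2)
    m_sk = Y.mean(axis=1)

    ss = {}
    ss["G"] = nJ * nK * n * ((m_g - grand) ** 2).sum()
    ss["subj"] = nJ * nK * ((m_s - m_g[g_of]) ** 2).sum()
    ss["J"] = S * nK * ((m_j - grand) ** 2).sum()
    ss["GJ"] = nK * n * ((m_gj - m_g[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss["Jsubj"] = nK * ((m_sj - m_s[:, None] - m_gj[g_of]
                         + m_g[g_of][:, None]) ** 2).sum()
    ss["K"] = S * nJ * ((m_k - grand) ** 2).sum()
    ss["GK"] = nJ * n * ((m_gk - m_g[:, None] - m_k[None, :] + grand) ** 2).sum()
    ss["Ksubj"] = nJ * ((m_sk - m_s[:, None] - m_gk[g_of]
                         + m_g[g_of][:, None]) ** 2).sum()
    ss["JK"] = S * ((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2).sum()
    ss["GJK"] = n * ((m_gjk - m_gj[:, :, None] - m_gk[:, None, :] - m_jk[None]
                      + m_g[:, None, None] + m_j[None, :, None]
                      + m_k[None, None, :] - grand) ** 2).sum()
    sstot = ((Y - grand) ** 2).sum()
    ss["JKsubj"] = sstot - sum(ss[key] for key in
                               ["G", "subj", "J", "GJ", "Jsubj", "K", "GK",
                                "Ksubj", "JK", "GJK"])

    dfs = {
        "G": (nG - 1, S - nG), "J": (nJ - 1, (nJ - 1) * (S - nG)),
        "GJ": ((nG - 1) * (nJ - 1), (nJ - 1) * (S - nG)),
        "K": (nK - 1, (nK - 1) * (S - nG)),
        "GK": ((nG - 1) * (nK - 1), (nK - 1) * (S - nG)),
        "JK": ((nJ - 1) * (nK - 1), (nJ - 1) * (nK - 1) * (S - nG)),
        "GJK": ((nG - 1) * (nJ - 1) * (nK - 1),
                (nJ - 1) * (nK - 1) * (S - nG)),
    }
    err_of = {"G": "subj", "J": "Jsubj", "GJ": "Jsubj", "K": "Ksubj",
              "GK": "Ksubj", "JK": "JKsubj", "GJK": "JKsubj"}
    return {
        eff: (ss[eff], ss[err_of[eff]], dfs[eff][0], dfs[eff][1])
        for eff in err_of
    }
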