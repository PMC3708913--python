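"""Independent oracles used by the tests.

These deliberately re-derive quantities by brute force or closed form,
sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

HAPS_2LOCUS = list(itertools.product((0, 1), (0, 1)))


def _genotype_classes(doses: np.ndarray):
    """Unique 2-locus dose vectors with their compatible haplotype pairs."""
    uniq, counts = np.unique(doses, axis=0, return_counts=True)
    classes = []
    for g, n in zip(uniq, counts):
        pairs = [
            (i, j, 1.0 if i == j else 2.0)
            for i in range(4)
            for j in range(i, 4)
            if all(HAPS_2LOCUS[i][l] + HAPS_2LOCUS[j][l] == g[l] for l in range(2))
        ]
        classes.append((pairs, int(n)))
    return classes


def grid_mle_2locus(doses: np.ndarray) -> np.ndarray:
    """Brute-force maximizer of the 2-locus multinomial haplotype likelihood.

    Searches the 4-haplotype frequency simplex on successively refined
    grids (final resolution 2e-4).  Haplotype order matches the binary
    enumeration (0,0), (0,1), (1,0), (1,1) of minor-allele indicators.
    """
    classes = _genotype_classes(doses)

    def loglik(F: np.ndarray) -> np.ndarray:
        ll = np.zeros(len(F))
        for pairs, n in classes:
            P = np.zeros(len(F))
            for i, j, m in pairs:
                P += m * F[:, i] * F[:, j]
            ll += n * np.log(P + 1e-300)
        return ll

    best = np.full(4, 0.25)
    for step, span in ((0.02, 1.0), (0.002, 0.04), (0.0002, 0.004)):
        axes = [np.arange(max(0.0, b - span), min(1.0, b + span) + step / 2, step)
                for b in best[:3]]
        g = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        f4 = 1.0 - g.sum(axis=1)
        m = f4 >= -1e-12
        F = np.column_stack([g[m], np.clip(f4[m], 0.0, None)])
        best = F[np.argmax(loglik(F))]
    return best
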