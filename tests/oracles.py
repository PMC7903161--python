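"""Independent brute-force oracles used to cross-check the main routines."""

import numpy as np


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.standard_normal((n, 2 * n))
    return m @ m.T / (2 * n) + 1e-3 * np.eye(n)


def gevd_eigenvalues_bruteforce(
    A: np.ndarray, B: np.ndarray, n_grid: int = 20000, n_bisect: int = 80
) -> np.ndarray:
    """Roots of det(A - lambda*B) located by sign-change scanning.

    Only suitable for small well-separated spectra (n <= 5); deliberately
    avoids any eigenvalue routine.
    """
    n = A.shape[0]
    # all generalized eigenvalues lie within +/- bound for SPD B
    bound = np.linalg.norm(A, 2) / np.linalg.eigvalsh(B).min() * 1.001 + 1.0

    def f(lam: float) -> float:
        return np.linalg.det(A - lam * B)

    grid = np.linspace(-bound, bound, n_grid)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
            continue
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            lo, hi = grid[i], grid[i + 1]
            flo = vals[i]
            for _ in range(n_bisect):
                mid = (lo + hi) / 2
                fm = f(mid)
                if np.sign(fm) == np.sign(flo):
                    lo, flo = mid, fm
                else:
                    hi = mid
            roots.append((lo + hi) / 2)
    roots = np.sort(np.array(roots))
    if roots.size != n:
        raise RuntimeError(
            f"oracle found {roots.size} roots, expected {n} (degenerate case?)"
        )
    return roots
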