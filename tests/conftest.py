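import itertools

import numpy as np
import pytest

from mirfsh import pipeline, simulate, targets


@pytest.fixture(scope="session")
def sim_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def energy_params() -> targets.EnergyParameters:
    return targets.load_energy_parameters()


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full deterministic pipeline run on the synthetic fixture."""
    out = tmp_path_factory.mktemp("demo")
    cfg = pipeline.PipelineConfig(outdir=out, seed=1)
    manifest = pipeline.run_pipeline(cfg)
    return cfg, manifest


def brute_force_duplex_mfe(s1: str, s2: str, params: targets.EnergyParameters):
    """Exhaustive enumeration over all antiparallel non-crossing pairings
    (>= 2 base pairs): the independent oracle for the duplex DP."""
    s1 = targets.to_rna(s1)
    s2 = targets.to_rna(s2)
    m, n = len(s1), len(s2)
    r = s2[::-1]
    allowed = {
        (i, k)
        for i in range(m)
        for k in range(n)
        if (s1[i], r[k]) in targets.ALLOWED_PAIRS
    }
    best = None
    for size in range(2, min(m, n) + 1):
        for iset in itertools.combinations(range(m), size):
            for kset in itertools.combinations(range(n), size):
                pairs = list(zip(iset, kset))
                if any(p not in allowed for p in pairs):
                    continue
                energy = params.duplex_init
                feasible = True
                for (i1, k1), (i2, k2) in zip(pairs, pairs[1:]):
                    l1, l2 = i2 - i1 - 1, k2 - k1 - 1
                    if l1 > params.max_loop or l2 > params.max_loop:
                        feasible = False
                        break
                    if l1 == 0 and l2 == 0:
                        energy += params.stack_energies[(s1[i1] + r[k1], s1[i2] + r[k2])]
                    else:
                        energy += params.loop_open + params.loop_per_nt * (l1 + l2)
                if feasible and (best is None or energy < best):
                    best = energy
    return best


def brute_force_lowess(x, y, span, iterations):
    """Naive re-implementation of the robust local-linear smoother used for
    MA normalization, written independently of the package's vectorized path:
    plain loops, explicit weighted least squares via np.polyfit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, min(n, int(round(span * n))))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust = np.ones(n)
    fit = np.zeros(n)
    for sweep in range(iterations + 1):
        for i in range(n):
            lo = hi = i
            while hi - lo + 1 < k:
                left_gap = xs[i] - xs[lo - 1] if lo > 0 else np.inf
                right_gap = xs[hi + 1] - xs[i] if hi < n - 1 else np.inf
                if left_gap <= right_gap:
                    lo -= 1
                else:
                    hi += 1
            d = np.abs(xs[lo : hi + 1] - xs[i])
            dmax = d.max()
            if dmax > 0:
                u = np.minimum(d / dmax, 1.0)
                w = (1 - u**3) ** 3
            else:
                w = np.ones_like(d)
            w = w * robust[lo : hi + 1]
            if w.sum() <= 0:
                fit[i] = ys[i]
                continue
            xw, yw = xs[lo : hi + 1], ys[lo : hi + 1]
            xbar = np.average(xw, weights=w)
            sxx = np.sum(w * (xw - xbar) ** 2)
            if sxx <= 1e-12 * max(1.0, xbar * xbar):
                fit[i] = np.average(yw, weights=w)
            else:
                b1, b0 = np.polyfit(xw, yw, 1, w=np.sqrt(w))
                fit[i] = b0 + b1 * xs[i]
        if sweep == iterations:
            break
        resid = ys - fit
        s = np.median(np.abs(resid))
        if s < 1e-10:
            robust = (np.abs(resid) <= 1e-8 * max(1.0, np.median(np.abs(ys)))).astype(float)
            if robust.sum() < 2:
                robust = np.ones(n)
        else:
            robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    out = np.empty(n)
    out[order] = fit
    return out
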