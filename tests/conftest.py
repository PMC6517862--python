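import numpy as np
import pytest

from eaccd.cohort import CaseRecord


def make_cases(times, events, t="T1", n="N0", m="M0", a="A1", prefix="c"):
    return [
        CaseRecord(id=f"{prefix}{i}", t_level=t, n_level=n, m_level=m,
                   surv_months=int(tt), event=int(ee), a_level=a)
        for i, (tt, ee) in enumerate(zip(times, events))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_group_cohort():
    """9 combinations in 3 well-separated latent hazard groups (HR 5 apart)."""
    from eaccd.synthetic import SimCell, SimDesign, generate

    cells = []
    lam = 0.002
    for g in range(1, 4):
        for i, (n_lvl, m_lvl) in enumerate([("N0", "M0"), ("N1a", "M0"), ("N1b", "M0")]):
            cells.append(SimCell({"T": f"T{g}", "N": n_lvl, "M": m_lvl, "A": "A1"},
                                 200, g))
    design = SimDesign(cells=cells,
                       hazards={1: lam, 2: 5 * lam, 3: 25 * lam},
                       seed=777)
    return generate(design)
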