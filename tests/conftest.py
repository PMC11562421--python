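import numpy as np
import pytest

from panelnet import GroundTruth, PanelDataset, VariableMeta


@pytest.fixture
def small_panel():
    """5 persons x 3 waves x 2 variables with monotone dropout for person 4."""
    values = np.array([
        [[0.1, 1.0], [0.2, 1.1], [0.3, 1.2]],
        [[0.5, 0.4], [0.6, 0.5], [0.7, 0.6]],
        [[1.0, 0.0], [1.1, 0.1], [1.2, 0.2]],
        [[0.3, 0.9], [0.4, 1.0], [np.nan, np.nan]],
        [[0.8, 0.2], [0.9, 0.3], [1.0, 0.4]],
    ])
    return PanelDataset(
        values=values,
        person_ids=np.array([1, 2, 3, 4, 5]),
        wave_times=np.array([1.0, 2.0, 3.0]),
        variables=[VariableMeta("A", "internalizing"),
                   VariableMeta("B", "externalizing")],
    )


def sparse_truth_p4() -> GroundTruth:
    """Handcrafted sparse ground truth used by the recovery harnesses.

    Three temporal cross-edges of 0.3 on an AR(0.25) diagonal, a chain of
    contemporaneous partials, and three between-person partials of 0.3 with a
    trait share of ~0.7 of unit within-variance.
    """
    p = 4
    B = np.eye(p) * 0.25
    B[1, 0] = 0.3
    B[2, 3] = 0.3
    B[3, 1] = 0.3
    P = np.zeros((p, p))
    P[0, 1] = P[1, 0] = 0.2
    P[1, 2] = P[2, 1] = 0.2
    P[2, 3] = P[3, 2] = 0.2
    K = -P.copy()
    np.fill_diagonal(K, 1.0)
    PB = np.zeros((p, p))
    PB[0, 2] = PB[2, 0] = 0.3
    PB[1, 3] = PB[3, 1] = 0.3
    PB[0, 3] = PB[3, 0] = -0.3
    KB = -PB.copy()
    np.fill_diagonal(KB, 1.0)
    SB = np.linalg.inv(KB)
    d = 1.0 / np.sqrt(np.diag(SB))
    Sigma_B = 0.7 * SB * np.outer(d, d)
    return GroundTruth(B=B, K_zeta=K, Sigma_B=Sigma_B,
                       trend_lin=0.0, trend_quad=0.0, mu=0.0)
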