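import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phenoselect.profiling import profile_screen
from phenoselect.simulate import SyntheticScreenConfig, generate_screen

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---- independent oracles (kept deliberately naive) -------------------------

def ecdf_value(sample, x) -> float:
    """F(x) by direct counting."""
    sample = list(sample)
    return sum(1 for v in sample if v <= x) / len(sample)


def oracle_sup_diff(a, b) -> float:
    """sup_x [F_a(x) - F_b(x)] by exhaustive evaluation at every sample point."""
    pts = list(a) + list(b)
    return max(ecdf_value(a, p) - ecdf_value(b, p) for p in pts)


def oracle_signed_ks(treated, control) -> float:
    d_plus = oracle_sup_diff(control, treated)
    d_minus = oracle_sup_diff(treated, control)
    return d_plus if d_plus >= d_minus else -d_minus


@pytest.fixture(scope="session")
def small_screen():
    """A small planted screen: line L1 stronger than L2 on every MOA."""
    a = np.tile([[2.0, 0.6]], (6, 1))
    cfg = SyntheticScreenConfig(
        n_cell_lines=2, n_features=12, n_active_features=4,
        n_moas=6, compounds_per_moa=4, cells_per_well=80,
        n_dmso_wells_per_plate=6, compound_wells_per_plate=12,
        effect_magnitude=a, heterogeneity=0.3, seed=42,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_screen):
    return profile_screen(small_screen.cells)


def make_profile_frame(entries, n_features=2):
    """Build a canonical profile table from (line, treatment, role, vector) tuples."""
    from phenoselect.io import CELL_LINE, ROLE, TREATMENT

    rows = []
    for line, treatment, role, vec in entries:
        row = {
            CELL_LINE: line, TREATMENT: treatment, ROLE: role,
            "n_cells_treated": 10, "n_cells_control": 10,
        }
        row.update({f"f_{j + 1}": v for j, v in enumerate(vec)})
        rows.append(row)
    return pd.DataFrame(rows)
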