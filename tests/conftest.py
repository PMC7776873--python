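import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import archhist as ah

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SCAFFOLD_LEN = 69


def make_seq(overrides: dict[int, str] | None = None, length: int = SCAFFOLD_LEN,
             fill: str = "G") -> str:
    """A fixed-length sequence with 1-based positional overrides."""
    chars = [fill] * length
    for pos, ch in (overrides or {}).items():
        chars[pos - 1] = ch
    return "".join(chars)


def identity_alignment(rows: dict[str, str], reference_id: str,
                       species=None) -> tuple[ah.AlignedCatalog, ah.PositionMap]:
    """Ungapped alignment from id->sequence with an identity position map."""
    ids = tuple(rows)
    aligned = ah.AlignedCatalog(
        ids=ids,
        rows=tuple(rows.values()),
        species_of=species or {i: i for i in ids},
        column_kept_mask=np.ones(len(next(iter(rows.values()))), dtype=bool),
    )
    return aligned, ah.build_position_map(aligned, reference_id)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic catalog shared by read-only tests."""
    spec = ah.SyntheticSpec(seed=7, n_single_species=30, n_multi_species=25)
    return spec, ah.gen_catalog(spec)
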