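import numpy as np
import pytest

from pqsar import (AADTable, PeptidePanel, PeptideRecord, STANDARD_RESIDUES,
                   SyntheticPanelSpec, generate_panel, log_transform)


def make_random_table(m: int, seed: int = 0, name: str = "rand") -> AADTable:
    """A valid descriptor table with m components and distinct residue rows."""
    rng = np.random.default_rng(seed)
    values = {r: tuple(rng.normal(size=m)) for r in STANDARD_RESIDUES}
    return AADTable(name=name, property_class="other", m=m, values=values)


@pytest.fixture
def toy_table() -> AADTable:
    """m=2 table with A=(1,0), C=(0,1) and distinct vectors elsewhere."""
    values = {"A": (1.0, 0.0), "C": (0.0, 1.0)}
    for i, r in enumerate(STANDARD_RESIDUES):
        if r not in values:
            values[r] = (float(i + 2), float(i * i + 3))
    return AADTable(name="toy2d", property_class="other", m=2, values=values)


@pytest.fixture
def small_panel() -> PeptidePanel:
    """Five-record hand-written panel, already valid and log-transformed."""
    records = tuple(
        PeptideRecord(sequence=s, blu=b)
        for s, b in [("ACDEF", 10.0), ("GHIKL", 100.0), ("MNPQR", 1000.0),
                     ("STVWY", 50.0), ("AAAAA", 5.0)]
    )
    return log_transform(PeptidePanel(panel_id="small", records=records))


def linear_panel(seed: int, n: int = 300, motif: str = "xxxTxV",
                 target_r2: float | None = None, noise_sd: float | None = 0.0,
                 **kw):
    """Synthetic linear panel plus ground truth (noiseless by default)."""
    spec = SyntheticPanelSpec(
        motif=motif, n=n, seed=seed, target_r2=target_r2, noise_sd=noise_sd,
        **kw,
    )
    return generate_panel(spec)
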