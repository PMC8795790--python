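"""Synthetic SLiM-panel generator with a planted, noise-capped signal.

SPOT-array intensities are an indirect, arbitrary-unit affinity readout, so
even a perfect model cannot explain all of their variance.  This module
generates motif-constrained peptide panels whose LogBLU response is a
planted function of the peptides' descriptor features plus Gaussian noise
calibrated to a chosen explained-variance ceiling, so the recoverable
signal fraction is known by construction.

Motif patterns use ``x`` for a free position (uniform over the 20 standard
residues by default), an uppercase letter for a fixed residue (e.g. the two
prolines of an SH3-like PxxP), and lowercase ``s``/``t`` for a fixed
phospho-serine/-threonine site (14-3-3-like panels).

The latent score mixes a linear term in the encoded features with an
optional pairwise-product term (a simple proxy for residue-residue
interplay); ``nonlinear_mix`` is the fraction of signal variance carried by
the products.  The score is standardized to unit variance, so a target
ceiling r^2 maps to noise SD sqrt(1/r^2 - 1) on the LogBLU scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import aad
from .panels import PeptidePanel, PeptideRecord, write_panel

#: mean LogBLU about which synthetic panels are centered (BLU ~ 10^3)
BASELINE_LOGBLU = 3.0

#: default generative descriptor table: VHSE whitened over the residue
#: alphabet, so feature collinearity cannot eat into the planted ceiling
#: (the target explained-variance fraction is then exactly what a linear
#: model in the encoded features can recover)
DEFAULT_TABLE = "VHSE_ortho"


def _resolve_table(name: str):
    try:
        return aad.get_table(name)
    except aad.AADError:
        if name == DEFAULT_TABLE:
            table = aad.decorrelated_table("VHSE", DEFAULT_TABLE)
            aad.register_table(table)
            return table
        raise

#: motif patterns mimicking the three reference domain classes
MOTIFS = {
    "SH3": "xxPxxPxxxx",   # PxxP polyproline-II core
    "PDZ": "xxxTxV",       # class-I C-terminus: S/T at -2, hydrophobe at 0
    "14-3-3": "xxRxxsxPxx",  # central phosphoserine site
}

_FREE = "x"


class MotifError(ValueError):
    """Raised for malformed motif patterns."""


def parse_motif(motif: str) -> list[str | None]:
    """Per-position constraint: None for free, otherwise the fixed code."""
    out = []
    for ch in motif:
        if ch == _FREE:
            out.append(None)
        elif ch in aad.STANDARD_RESIDUES or ch in aad.PARENT_RESIDUE:
            out.append(ch)
        else:
            raise MotifError(
                f"motif symbol {ch!r} is neither 'x', a standard residue "
                "nor a phospho code (s/t)"
            )
    if not out:
        raise MotifError("empty motif")
    return out


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Recipe for one synthetic panel; exactly one of noise_sd / target_r2."""

    motif: str
    n: int
    seed: int
    table_name: str = DEFAULT_TABLE
    beta: object = "random"          # "random" or explicit (L*m,) vector
    beta_density: float = 1.0        # fraction of nonzero random coefficients
    nonlinear_mix: float = 0.0       # signal-variance fraction from products
    n_pairs: int | None = None       # product pairs; default L//2 + 2
    noise_sd: float | None = None
    target_r2: float | None = None
    residue_freqs: tuple | None = None  # free-position composition; uniform if None
    panel_id: str = ""
    domain_class: str = "other"
    domain_name: str = ""
    domain_index: str = "1/1"
    species: str = ""

    def __post_init__(self):
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise ValueError("set exactly one of noise_sd / target_r2")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_r2 is not None and not (0 < self.target_r2 <= 1):
            raise ValueError("target_r2 must be in (0, 1]")
        if not 0 <= self.nonlinear_mix <= 1:
            raise ValueError("nonlinear_mix must be in [0, 1]")
        if self.n < 2:
            raise ValueError("need at least 2 peptides")
        parse_motif(self.motif)  # validates

    @property
    def length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: coefficients, latent scores, noise level."""

    beta: np.ndarray
    latent: np.ndarray
    noise_sd: float
    realized_signal_fraction: float
    pairs: tuple
    seed: int
    spec: SyntheticPanelSpec = field(repr=False)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(
            "degenerate latent score (zero variance); the motif leaves no "
            "informative free positions for the chosen coefficients"
        )
    return (v - v.mean()) / sd


def _latent_scores(spec: SyntheticPanelSpec, sequences, table, rng):
    """Unit-variance latent score s and its ingredients for given sequences."""
    from .encoding import encode_peptide

    X = np.array([encode_peptide(s, table) for s in sequences])
    mean, sd = X.mean(axis=0), X.std(axis=0)
    varying = sd > 0
    Z = np.zeros_like(X)
    Z[:, varying] = (X[:, varying] - mean[varying]) / sd[varying]

    if isinstance(spec.beta, str) and spec.beta == "random":
        beta = rng.normal(size=X.shape[1])
        if spec.beta_density < 1.0:
            keep = rng.random(X.shape[1]) < spec.beta_density
            beta = np.where(keep, beta, 0.0)
    else:
        beta = np.asarray(spec.beta, dtype=float)
        if beta.shape != (X.shape[1],):
            raise ValueError(
                f"beta must have length L*m = {X.shape[1]}, got {beta.shape}"
            )
    z_lin = _standardize(Z @ beta)

    lam = spec.nonlinear_mix
    var_idx = np.flatnonzero(varying)
    n_pairs = spec.n_pairs if spec.n_pairs is not None else spec.length // 2 + 2
    pairs = tuple(
        tuple(rng.choice(var_idx, 2, replace=False)) for _ in range(n_pairs)
    )
    if lam > 0:
        z_nl = _standardize(
            sum(Z[:, i] * Z[:, j] for i, j in pairs)
        )
        s = math.sqrt(1 - lam) * z_lin + math.sqrt(lam) * z_nl
    else:
        s = z_lin
    return _standardize(s), beta, pairs


def _sample_sequences(spec: SyntheticPanelSpec, rng) -> list[str]:
    slots = parse_motif(spec.motif)
    residues = list(aad.STANDARD_RESIDUES)
    freqs = None
    if spec.residue_freqs is not None:
        freqs = np.asarray(spec.residue_freqs, dtype=float)
        if freqs.shape != (20,) or freqs.min() < 0 or freqs.sum() <= 0:
            raise ValueError("residue_freqs must be 20 non-negative weights")
        freqs = freqs / freqs.sum()
    draws = rng.choice(residues, size=(spec.n, len(slots)), p=freqs)
    return [
        "".join(fix if fix is not None else draws[i, j]
                for j, fix in enumerate(slots))
        for i in range(spec.n)
    ]


def generate_panel(spec: SyntheticPanelSpec):
    """Generate one panel and its ground truth; deterministic under the seed."""
    table = _resolve_table(spec.table_name)
    rng = np.random.default_rng(spec.seed)
    sequences = _sample_sequences(spec, rng)
    s, beta, pairs = _latent_scores(spec, sequences, table, rng)

    if spec.noise_sd is not None:
        noise_sd = float(spec.noise_sd)
    else:
        noise_sd = math.sqrt(1.0 / spec.target_r2 - 1.0)  # sd(s) == 1
    if noise_sd > 0:
        # sample-exact calibration: the noise draw is centered, made
        # orthogonal to the latent score and rescaled, so the realized
        # signal fraction matches the spec even in small panels
        eps = rng.normal(size=spec.n)
        eps = eps - eps.mean() - (eps @ s / (s @ s)) * s
        eps *= noise_sd / eps.std()
        y = BASELINE_LOGBLU + s + eps
        realized = float(s.var() / y.var())
    else:
        y = BASELINE_LOGBLU + s
        realized = 1.0

    records = tuple(
        PeptideRecord(sequence=seq, blu=float(10.0 ** yi), log_affinity=float(yi))
        for seq, yi in zip(sequences, y)
    )
    panel = PeptidePanel(
        panel_id=spec.panel_id or f"synthetic_{spec.seed}",
        domain_class=spec.domain_class,
        domain_name=spec.domain_name or f"synthetic-{spec.motif}",
        domain_index=spec.domain_index,
        species=spec.species or "synthetic",
        records=records,
    )
    truth = GroundTruth(
        beta=beta, latent=s, noise_sd=noise_sd,
        realized_signal_fraction=realized, pairs=pairs,
        seed=spec.seed, spec=spec,
    )
    return panel, truth


def calibrate_noise(spec: SyntheticPanelSpec, pilot_n: int = 2000) -> float:
    """Noise SD giving the spec's target ceiling: sd(s) * sqrt(1/r^2 - 1).

    The latent-score SD is estimated from a pilot panel under the spec's
    seed (it is 1 by construction, so this is a consistency check as much
    as an estimate).
    """
    if spec.target_r2 is None:
        raise ValueError("calibrate_noise needs a spec with target_r2 set")
    table = _resolve_table(spec.table_name)
    rng = np.random.default_rng(spec.seed)
    pilot = SyntheticPanelSpec(
        **{**spec.__dict__, "n": pilot_n}
    )
    sequences = _sample_sequences(pilot, rng)
    s, _, _ = _latent_scores(pilot, sequences, table, rng)
    return float(s.std() * math.sqrt(1.0 / spec.target_r2 - 1.0))


# ---------------------------------------------------------------------------
# fixture suite mirroring the 18 reference panels
# ---------------------------------------------------------------------------

#: (domain_class, domain_name, domain_index, species, n) rows; the 6,068-record
#: PSD95-like panel is scaled down to 1,500 and the largest SH3 panel to
#: 2,000 so the suite stays desk-sized.
FIXTURE_LAYOUT = (
    ("SH3", "Amphiphysin", "1/1", "Human", 884),
    ("SH3", "Amphiphysin", "1/1", "Yeast", 2000),
    ("SH3", "Boi1", "1/1", "Yeast", 1336),
    ("SH3", "Boi2", "1/1", "Yeast", 1312),
    ("SH3", "Endophilin", "1/1", "Yeast", 1998),
    ("SH3", "Myosin5", "1/1", "Yeast", 1139),
    ("SH3", "Rvs167", "1/1", "Yeast", 1369),
    ("SH3", "Sho1", "1/1", "Yeast", 1015),
    ("SH3", "Yfr024", "1/1", "Yeast", 1282),
    ("SH3", "Yhr016c", "1/1", "Yeast", 1348),
    ("PDZ", "CALP", "1/1", "Human", 80),
    ("PDZ", "NHERF1", "1/2", "Human", 77),
    ("PDZ", "NHERF1", "2/2", "Human", 80),
    ("PDZ", "NHERF2", "1/2", "Human", 80),
    ("PDZ", "NHERF2", "2/2", "Human", 80),
    ("PDZ", "SYNA1", "1/1", "Human", 56),
    ("PDZ", "PSD95", "1/1", "Human", 1500),
    ("14-3-3", "14-3-3", "1/1", "Yeast", 1163),
)


def make_fixture_suite(out_dir, base_seed: int = 20220114,
                       target_r2: float = 0.7, nonlinear_mix: float = 0.3):
    """Write 18 synthetic panels mirroring the reference panel registry.

    Each panel gets the motif of its domain class, the shared ceiling
    ``target_r2`` and a per-panel seed derived from ``base_seed``.  Panels
    are TSV files with metadata sidecars plus a ground-truth sidecar
    recording the planted coefficients and realized signal fraction.
    Reruns with the same seed are byte-identical.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (dclass, dname, didx, species, n) in enumerate(FIXTURE_LAYOUT, start=1):
        spec = SyntheticPanelSpec(
            motif=MOTIFS[dclass],
            n=n,
            seed=(base_seed + i) % (2 ** 31),
            nonlinear_mix=nonlinear_mix,
            target_r2=target_r2,
            panel_id=f"panel{i:02d}_{dname}_{species}".replace("/", "-"),
            domain_class=dclass,
            domain_name=dname,
            domain_index=didx,
            species=species,
        )
        panel, truth = generate_panel(spec)
        path = out_dir / f"{panel.panel_id}.tsv"
        write_panel(panel, path)
        with open(path.with_suffix(".truth.tsv"), "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"seed\t{spec.seed}\n")
            fh.write(f"motif\t{spec.motif}\n")
            fh.write(f"table_name\t{spec.table_name}\n")
            fh.write(f"target_r2\t{target_r2!r}\n")
            fh.write(f"nonlinear_mix\t{nonlinear_mix!r}\n")
            fh.write(f"noise_sd\t{truth.noise_sd!r}\n")
            fh.write(f"realized_signal_fraction\t{truth.realized_signal_fraction!r}\n")
            fh.write("beta\t" + ",".join(f"{b:.6f}" for b in truth.beta) + "\n")
        paths.append(path)
    return paths
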