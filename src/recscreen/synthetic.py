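"""Synthetic generators for every pipeline input, with planted ground truth.

The generators emulate the shape of the real inputs — perturbation z-score
signatures over a 10-cell-line panel at two timepoints, a basal-expression /
drug-sensitivity panel, a tumor survival cohort, two-channel fluorescence
micrographs, and viability-vs-dose tables — while planting known effects so
that every downstream stage can be validated against ground truth.  Every
generator is a pure function of (parameters, seed).

Conventions planted here and relied on downstream:

* Sensitivity is an AUC, lower = more sensitive.  "High expression is
  associated with sensitivity" therefore corresponds to a *negative*
  expression-vs-AUC correlation.
* A reversal compound shifts its target genes' z by ``reversal_effect``
  (negative = downregulation) in a random ``reversal_cell_fraction`` of cell
  lines, at both timepoints.
* Fused/fission image pairs hold total tube length (hence total fluorescent
  mass) constant, so morphology metrics rather than intensity separate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.measure import perimeter_crofton

from .core_io import (
    DEFAULT_CELL_LINES,
    DEFAULT_TIMEPOINTS,
    SignatureTensor,
    substream,
)

__all__ = [
    "PlantSpec",
    "make_signature_tensor",
    "make_sensitivity_panel",
    "make_survival_cohort",
    "make_mito_image",
    "make_condition_pair",
    "make_dose_response",
    "SyntheticMitoImage",
]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of the planted-effect synthetic screen.

    Defaults describe the demo screening condition: one known reversal
    compound among 200 inert compounds, two target genes, a strong planted
    downregulation (z shift -4) in all cell lines at both timepoints, and a
    planted basal-expression/sensitivity correlation of 0.9.
    """

    n_compounds: int = 201
    n_genes: int = 200
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    target_genes: tuple[str, ...] = ("MCM2", "MCM10")
    reversal_compounds: tuple[str, ...] = ("RVRSL-001",)
    reversal_effect: float = -4.0
    reversal_cell_fraction: float = 1.0
    corr_r: float = 0.9
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_genes < 1:
            raise ValueError("n_compounds and n_genes must be >= 1")
        if not 0.0 < self.reversal_cell_fraction <= 1.0:
            raise ValueError("reversal_cell_fraction must lie in (0, 1]")
        if not -1.0 <= self.corr_r <= 1.0:
            raise ValueError("corr_r must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.reversal_compounds) > self.n_compounds:
            raise ValueError("more reversal compounds than compounds")
        if len(self.target_genes) > self.n_genes:
            raise ValueError("more target genes than genes")

    @property
    def compounds(self) -> list[str]:
        n_null = self.n_compounds - len(self.reversal_compounds)
        return list(self.reversal_compounds) + [
            f"CPD-{i:04d}" for i in range(n_null)
        ]

    @property
    def genes(self) -> list[str]:
        n_bg = self.n_genes - len(self.target_genes)
        return list(self.target_genes) + [f"G{i:04d}" for i in range(n_bg)]


def make_signature_tensor(spec: PlantSpec, seed: int) -> SignatureTensor:
    """Background z ~ Normal(0, noise_sd); each reversal compound shifts each
    target gene by ``reversal_effect`` in a random fraction of cell lines at
    both timepoints."""
    rng = substream(seed, "signatures")
    compounds, genes = spec.compounds, spec.genes
    L, T = len(spec.cell_lines), len(spec.timepoints)
    z = rng.normal(0.0, spec.noise_sd, size=(spec.n_compounds, spec.n_genes, L, T))
    n_hit = max(1, int(round(spec.reversal_cell_fraction * L)))
    for ci, comp in enumerate(compounds):
        if comp not in spec.reversal_compounds:
            continue
        for tg in spec.target_genes:
            gi = genes.index(tg)
            lines = rng.choice(L, size=n_hit, replace=False)
            z[ci, gi, lines, :] += spec.reversal_effect
    return SignatureTensor.from_array(
        z, compounds, genes, list(spec.cell_lines), list(spec.timepoints)
    )


def make_sensitivity_panel(
    spec: PlantSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Basal expression (cell line x gene, log2 scale) and sensitivity AUC
    (compound x cell line) with a planted expression/sensitivity association.

    For every (target gene, reversal compound) pair, expression and AUC share
    a per-cell-line latent factor so that their correlation is exactly
    -|corr_r| in population ("higher expression -> more sensitive -> lower
    AUC"); all other pairs are independent.  At |corr_r| = 1 the pair is a
    degenerate (noise-free) linear relation.
    """
    if len(spec.cell_lines) < 3:
        raise ValueError(
            "need at least 3 cell lines (correlation undefined downstream)"
        )
    if abs(spec.corr_r) == 1.0 and spec.noise_sd != 0.0:
        raise ValueError("|corr_r| = 1 requires noise_sd = 0")
    rng = substream(seed, "sensitivity")
    L = len(spec.cell_lines)
    rho = abs(spec.corr_r)
    latent = rng.normal(size=L)

    expr = rng.normal(size=(L, spec.n_genes))
    genes = spec.genes
    for tg in spec.target_genes:
        gi = genes.index(tg)
        expr[:, gi] = math.sqrt(rho) * latent + math.sqrt(1 - rho) * rng.normal(size=L)

    auc = rng.normal(size=(spec.n_compounds, L))
    for ci, comp in enumerate(spec.compounds):
        if comp in spec.reversal_compounds:
            auc[ci, :] = -math.sqrt(rho) * latent + math.sqrt(1 - rho) * rng.normal(size=L)

    expr_df = pd.DataFrame(8.0 + expr, index=list(spec.cell_lines), columns=genes)
    expr_df.index.name = "cell_line"
    auc_df = pd.DataFrame(
        12.0 + auc, index=spec.compounds, columns=list(spec.cell_lines)
    )
    auc_df.index.name = "compound"
    return expr_df.sort_index().sort_index(axis=1), auc_df.sort_index().sort_index(axis=1)


def make_survival_cohort(
    n: int,
    hr: float,
    cutoff_q: float,
    censor_rate: float,
    seed: int,
    gene: str = "MCM2",
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Cohort with LogNormal expression and exponential event times whose
    hazard is multiplied by ``hr`` for patients above the ``cutoff_q``
    expression quantile; independent exponential censoring at
    ``censor_rate`` (0 disables censoring)."""
    if n < 10:
        raise ValueError("cohort size must be >= 10")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if not 0.0 < cutoff_q < 1.0:
        raise ValueError("cutoff_q must lie in (0, 1)")
    if censor_rate < 0:
        raise ValueError("censor_rate must be nonnegative")
    rng = substream(seed, "survival", gene)
    expr = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    high = expr > np.quantile(expr, cutoff_q)
    rate = base_hazard * np.where(high, hr, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            gene: expr,
        }
    )


# ---------------------------------------------------------------------------
# Mitochondrial micrographs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMitoImage:
    """Rendered image pair plus per-tube ground truth (pre-blur mask metrics).

    ``labels`` is the pre-blur tube label image (0 = background), the exact
    segmentation ground truth."""

    mito: np.ndarray
    nucleus: np.ndarray
    truth: pd.DataFrame = field(repr=False)
    labels: np.ndarray = field(repr=False, default=None)
    pixel_size_um: float = 1.0


def _draw_tube(
    rng: np.random.Generator,
    shape: tuple[int, int],
    length_px: float,
    width_px: float,
) -> np.ndarray:
    """Rasterize one smooth random curve of given length and width."""
    h, w = shape
    margin = int(width_px) + 2
    mask = np.zeros(shape, dtype=bool)
    r = rng.uniform(margin, h - margin)
    c = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, 2 * np.pi)
    radius = max(1.0, width_px / 2.0)
    n_steps = max(1, int(round(length_px)))
    for _ in range(n_steps):
        rr, cc = draw_disk((r, c), radius, shape=shape)
        mask[rr, cc] = True
        theta += rng.normal(0.0, 0.08)
        r_new, c_new = r + np.sin(theta), c + np.cos(theta)
        # reflect off the borders to stay on canvas
        if not margin <= r_new <= h - margin:
            theta = -theta
            r_new = r
        if not margin <= c_new <= w - margin:
            theta = np.pi - theta
            c_new = c
        r, c = r_new, c_new
    return mask


def make_mito_image(
    n_tubes: int,
    tube_len_px: tuple[float, float],
    width_px: float,
    psf_sigma: float,
    photon_scale: float,
    seed: int,
    canvas: tuple[int, int] = (512, 512),
    background: float = 5.0,
    pixel_size_um: float = 0.1,
) -> SyntheticMitoImage:
    """Render mitochondria as smooth random tubes, blur by a Gaussian PSF and
    apply Poisson shot noise; record per-tube ground-truth area/perimeter.

    ``tube_len_px`` is (mean, sd) of the per-tube curve length in pixels.
    Tubes are placed by rejection sampling so they do not touch; ground truth
    is exact on the pre-blur binary mask.
    """
    if canvas[0] < 256 or canvas[1] < 256:
        raise ValueError("canvas must be at least 256x256")
    rng = substream(seed, "mito", n_tubes, tube_len_px, width_px)
    mean_len, sd_len = tube_len_px
    expected_px = n_tubes * mean_len * width_px
    if expected_px > 0.5 * canvas[0] * canvas[1]:
        raise ValueError("overcrowded: tubes would cover > 50% of the canvas")

    occupancy = np.zeros(canvas, dtype=bool)
    records = []
    label_img = np.zeros(canvas, dtype=np.int32)
    for tube_id in range(1, n_tubes + 1):
        length = max(2.0, rng.normal(mean_len, sd_len)) if sd_len > 0 else mean_len
        placed = False
        for _ in range(200):
            mask = _draw_tube(rng, canvas, length, width_px)
            grown = ndimage.binary_dilation(mask, iterations=2)
            if not (grown & occupancy).any():
                placed = True
                break
        if not placed:  # dense field: accept the overlap, merged in truth
            mask = _draw_tube(rng, canvas, length, width_px)
        occupancy |= mask
        label_img[mask] = tube_id
        records.append(
            {
                "label": tube_id,
                "length_px": length,
                "area_px": int(mask.sum()),
                "perimeter_px": float(perimeter_crofton(mask, directions=4)),
            }
        )
    truth = pd.DataFrame(records)

    signal = ndimage.gaussian_filter(occupancy.astype(float), psf_sigma)
    lam = background + photon_scale * signal
    mito = rng.poisson(lam).astype(np.uint16)

    # nucleus: one soft disc, off-center
    nuc = np.zeros(canvas, dtype=float)
    rr, cc = draw_disk(
        (canvas[0] * 0.5, canvas[1] * 0.5), min(canvas) * 0.15, shape=canvas
    )
    nuc[rr, cc] = 1.0
    nuc = ndimage.gaussian_filter(nuc, 3.0)
    nucleus = rng.poisson(background + 4 * photon_scale * nuc).astype(np.uint16)

    return SyntheticMitoImage(
        mito=mito, nucleus=nucleus, truth=truth, labels=label_img,
        pixel_size_um=pixel_size_um,
    )


def make_condition_pair(
    seed: int,
    total_length_px: float = 480.0,
    n_fused: int = 6,
    n_fission: int = 24,
    width_px: float = 4.0,
    psf_sigma: float = 1.2,
    photon_scale: float = 30.0,
    canvas: tuple[int, int] = (512, 512),
) -> dict[str, SyntheticMitoImage]:
    """Fused vs fission image pair at matched total tube length.

    Fused: few long tubes.  Fission: many short tubes.  Total curve length
    (and so total fluorescent mass) is equal by construction, so per-object
    area and perimeter — not intensity — separate the conditions.
    """
    if n_fused >= n_fission:
        raise ValueError("fused condition must have fewer, longer tubes")
    fused = make_mito_image(
        n_fused, (total_length_px / n_fused, 0.0), width_px, psf_sigma,
        photon_scale, substream(seed, "fused").integers(2**31), canvas=canvas,
    )
    fission = make_mito_image(
        n_fission, (total_length_px / n_fission, 0.0), width_px, psf_sigma,
        photon_scale, substream(seed, "fission").integers(2**31), canvas=canvas,
    )
    return {"fused": fused, "fission": fission}


def make_dose_response(
    ic50: float,
    hill: float,
    doses: list[float] | tuple[float, ...] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Viability table from a logistic dose-response:
    viability = 100 / (1 + (d / ic50)^hill) + noise, dose 0 = 100% baseline."""
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    rng = substream(seed, "dose_response", ic50, hill)
    rows = []
    for d in doses:
        clean = 100.0 if d == 0 else 100.0 / (1.0 + (d / ic50) ** hill)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"dose": d, "viability": clean + noise, "replicate": rep})
    return pd.DataFrame(rows)
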