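"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the structure of the real inputs — a SMART-seq2-style
single-cell count matrix over a few dozen projection-neuron (PN) subtypes, S2
cell-binding micrographs, axis-gradient antennal-lobe images, and MARCM
clone-scoring tables — so that QC, profiling, screening, image quantification
and penetrance statistics can all be tested against a known answer.

Count model
-----------
Each gene gets a per-subtype "intensity" on the log2(CPM+1) scale.
Cell-surface-molecule (CSM) candidates follow an on/off bimodal pattern
across subtypes — the regime in which both an intensity matrix and a
detection-fraction ("breadth") matrix are informative. Background genes get
intensities whose implied proportions are roughly self-consistent with the
CPM scale at the default gene count. A planted
partner gene's intensity vector is a decreasing affine transform of the target
gene's vector, interpolated by a strength parameter in [0, 1] toward an
independent random profile (strength 1 = exact negative affine relation, hence
Pearson r = -1 across subtypes before sampling). Per cell, intensities are
converted to relative transcript abundances, scaled to a log-normal library
size, sampled as negative-binomial counts, and thinned by independent dropout.
Mitochondrial ("mt:" prefix) and ERCC spike-in ("ERCC-" prefix) genes receive
per-cell fractions of the library drawn from configured intervals.

A single seed fans out through ``numpy.random.SeedSequence`` substreams so the
profile layout and the count noise are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ImageStack
from .errors import ConfigurationError, GenerationError

MITO_PREFIX = "mt:"
ERCC_PREFIX = "ERCC-"

_DEFAULT_MARKERS = ("elav", "nSyb", "Syt1")


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the synthetic single-cell count matrix.

    Defaults describe a study-scale dataset: ~40 PN subtypes with tens of
    cells each, deep full-length libraries (mean 3e5 counts, so the 1e5
    QC filter trims a tail rather than the bulk), small mitochondrial and
    spike-in fractions, and one planted anti-correlated CSM pair
    (caps -> Ten-m) hidden among random decoy CSMs.
    """

    n_subtypes: int = 40
    cells_per_subtype: int = 30
    n_genes: int = 1000
    n_csms: int = 40
    planted_pairs: tuple[tuple[str, str, float], ...] = (("caps", "Ten-m", 1.0),)
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.15
    library_size_mean: float = 3e5
    library_size_sigma: float = 0.25
    mito_fraction_range: tuple[float, float] = (0.005, 0.03)
    ercc_fraction_range: tuple[float, float] = (0.005, 0.02)
    n_mito: int = 10
    n_ercc: int = 20
    markers: tuple[str, ...] = _DEFAULT_MARKERS
    csm_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subtypes", "cells_per_subtype", "n_genes", "n_csms",
                     "n_mito", "n_ercc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        for name in ("mito_fraction_range", "ercc_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must be an interval within [0, 1]")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ConfigurationError("nb_dispersion and library_size_mean must be positive")
        targets = [t for t, _, _ in self.planted_pairs]
        partners = [p for _, p, _ in self.planted_pairs]
        ids = targets + partners
        if len(set(ids)) != len(ids):
            raise ConfigurationError("planted gene ids must be distinct")
        for t, p, s in self.planted_pairs:
            if not (0.0 <= s <= 1.0):
                raise ConfigurationError(f"anti-correlation strength for ({t}, {p}) not in [0, 1]")
        if self.csm_names is not None:
            missing = [g for g in ids if g not in self.csm_names]
            if missing:
                raise ConfigurationError(f"planted pair references unknown gene(s): {missing}")
            if len(self.csm_names) != self.n_csms:
                raise ConfigurationError("csm_names length must equal n_csms")
        overhead = self.n_csms + len(self.markers) + self.n_mito + self.n_ercc
        if self.n_genes < overhead + 1:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {overhead} CSM/marker/mito/ERCC genes"
            )


@dataclass(frozen=True)
class PlantedCell:
    """Geometry and intensities of one synthetic cell in a binding image."""

    kind: str                      # "transfected" | "control"
    center: tuple[float, float]    # (row, col) pixels
    nuclear_radius_um: float
    body_radius_um: float
    intensity: Mapping[str, float]  # per channel name
    shape: str = "disk"            # "disk" | "bar"
    bar_size_px: tuple[int, int] | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Immutable record of what was planted, keyed so tests can resolve it."""

    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    gene_means: pd.DataFrame | None = None        # planted log2-intensity, subtype x gene
    expected_log_cpm: pd.DataFrame | None = None  # post-normalization expectation
    cells: tuple[PlantedCell, ...] = ()
    gradient: Mapping[str, float] | None = None
    penetrance: Mapping[str, tuple[float, Mapping[str, float]]] | None = None


# --------------------------------------------------------------------------
# single-cell counts
# --------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and var = mean + mean^2/dispersion."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def gen_sc_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cells x genes count matrix with a planted anti-correlated pair.

    Returns an :class:`anndata.AnnData` (sparse integer ``X``, ``obs['subtype']``
    labels, boolean gene flags in ``var``) and the :class:`GroundTruth`.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_prof, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))

    planted_ids = [g for pair in config.planted_pairs for g in pair[:2]]
    if config.csm_names is not None:
        csm_ids = list(config.csm_names)
    else:
        n_decoys = config.n_csms - len(planted_ids)
        if n_decoys < 0:
            raise ConfigurationError("n_csms smaller than number of planted genes")
        csm_ids = planted_ids + [f"CSM{i:03d}" for i in range(n_decoys)]
    marker_ids = list(config.markers)
    n_bg = config.n_genes - config.n_csms - len(marker_ids) - config.n_mito - config.n_ercc
    bg_ids = [f"gene{i:04d}" for i in range(n_bg)]
    mito_ids = [f"{MITO_PREFIX}gene{i:02d}" for i in range(config.n_mito)]
    ercc_ids = [f"{ERCC_PREFIX}{i:05d}" for i in range(config.n_ercc)]
    gene_ids = csm_ids + marker_ids + bg_ids + mito_ids + ercc_ids
    cellular_ids = csm_ids + marker_ids + bg_ids

    T = config.n_subtypes
    subtypes = [f"PN{t:02d}" for t in range(T)]

    # planted log2-intensity profiles for cellular genes
    M = np.empty((T, len(cellular_ids)))
    col = {g: j for j, g in enumerate(cellular_ids)}
    on = rng_prof.random((T, config.n_csms)) < 0.5
    M[:, : config.n_csms] = np.where(
        on,
        rng_prof.uniform(5.0, 10.0, size=(T, config.n_csms)),
        rng_prof.uniform(0.0, 2.0, size=(T, config.n_csms)),
    )
    M[:, config.n_csms : config.n_csms + len(marker_ids)] = 13.0
    base = rng_prof.uniform(6.0, 12.0, size=n_bg)
    M[:, config.n_csms + len(marker_ids):] = np.clip(
        base[None, :] + rng_prof.normal(0.0, 1.0, size=(T, n_bg)), 0.0, None
    )
    for target, partner, strength in config.planted_pairs:
        t_on = rng_prof.random(T) < 0.5
        tgt = np.where(t_on, rng_prof.uniform(5.0, 10.0, size=T),
                       rng_prof.uniform(0.0, 2.0, size=T))
        mirror = (tgt.min() + tgt.max()) - tgt   # exact decreasing affine transform
        a_on = rng_prof.random(T) < 0.5
        alt = np.where(a_on, rng_prof.uniform(5.0, 10.0, size=T),
                       rng_prof.uniform(0.0, 2.0, size=T))
        M[:, col[target]] = tgt
        M[:, col[partner]] = strength * mirror + (1.0 - strength) * alt

    w_mito = rng_prof.dirichlet(np.ones(config.n_mito))
    w_ercc = rng_prof.dirichlet(np.ones(config.n_ercc))

    n_cells = T * config.cells_per_subtype
    labels = np.repeat(subtypes, config.cells_per_subtype)
    mu_log = np.log(config.library_size_mean) - config.library_size_sigma**2 / 2
    libs = rng_counts.lognormal(mu_log, config.library_size_sigma, size=n_cells)
    f_m = rng_counts.uniform(*config.mito_fraction_range, size=n_cells)
    f_e = rng_counts.uniform(*config.ercc_fraction_range, size=n_cells)

    rel = np.power(2.0, M) - 1.0                     # (T, G_cellular)
    rel_hat = rel / rel.sum(axis=1, keepdims=True)

    subtype_idx = np.repeat(np.arange(T), config.cells_per_subtype)
    mean_mat = np.empty((n_cells, len(gene_ids)))
    n_cell_genes = len(cellular_ids)
    mean_mat[:, :n_cell_genes] = (
        rel_hat[subtype_idx] * (libs * (1.0 - f_m - f_e))[:, None]
    )
    mean_mat[:, n_cell_genes : n_cell_genes + config.n_mito] = (
        w_mito[None, :] * (libs * f_m)[:, None]
    )
    mean_mat[:, n_cell_genes + config.n_mito:] = w_ercc[None, :] * (libs * f_e)[:, None]

    counts = _nb_sample(rng_counts, mean_mat, config.nb_dispersion)
    if config.dropout_rate > 0:
        keep = rng_counts.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(
            {"subtype": pd.Categorical(labels)},
            index=[f"cell{i:04d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(
            {
                "is_csm": [g in set(csm_ids) for g in gene_ids],
                "is_mito": [g.startswith(MITO_PREFIX) for g in gene_ids],
                "is_ercc": [g.startswith(ERCC_PREFIX) for g in gene_ids],
                "is_marker": [g in set(marker_ids) for g in gene_ids],
            },
            index=gene_ids,
        ),
    )

    # expectation of log2(CPM+1) for cellular genes given mean fractions
    f_cell = 1.0 - np.mean(config.mito_fraction_range) - np.mean(config.ercc_fraction_range)
    exp_cpm = 1e6 * f_cell * rel_hat
    truth = GroundTruth(
        planted_pairs=config.planted_pairs,
        gene_means=pd.DataFrame(M, index=subtypes, columns=cellular_ids),
        expected_log_cpm=pd.DataFrame(
            np.log2(exp_cpm + 1.0), index=subtypes, columns=cellular_ids
        ),
    )
    return adata, truth


# --------------------------------------------------------------------------
# binding images
# --------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _bar_mask(shape: tuple[int, int], center: tuple[float, float], size_px: tuple[int, int]) -> np.ndarray:
    h, w = size_px
    r0 = int(round(center[0] - h / 2))
    c0 = int(round(center[1] - w / 2))
    mask = np.zeros(shape, dtype=bool)
    mask[max(r0, 0) : r0 + h, max(c0, 0) : c0 + w] = True
    return mask


def gen_cell_image(
    n_transfected: int = 5,
    n_control: int = 5,
    *,
    pixel_size_um: float = 0.1625,
    image_shape: tuple[int, int] = (512, 512),
    control_radius_um: float = 2.2,
    offgate_radii_um: Sequence[float] = (),
    n_bars: int = 0,
    body_radius_um: float = 4.0,
    fl_intensity: float = 200.0,
    ecd_transfected: float = 120.0,
    ecd_control: float = 15.0,
    nuclear_intensity: float = 180.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    n_planes: int = 1,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a three-channel binding scene of disk-shaped cells.

    Channels: ``fl`` (full-length receptor; transfected cells only), ``ecd``
    (soluble ectodomain signal), ``nuclear`` (DAPI-like). Control cells carry a
    nucleus of ``control_radius_um`` inside a larger uniform-ECD cell body so
    that the dilated nuclear ROI measures the planted ECD intensity exactly in
    the noiseless case. ``offgate_radii_um`` plants extra control nuclei whose
    areas fall outside the 7.8-23.4 um^2 gate; ``n_bars`` plants elongated
    nuclear-bright bars (in-gate area, low circularity).

    Cells are placed by rejection sampling without overlap; if placement fails
    a :class:`GenerationError` is raised.
    """
    rng = np.random.default_rng(seed)
    dilation_um = 1.25
    specs: list[dict] = []
    for _ in range(n_transfected):
        specs.append(
            {
                "kind": "transfected",
                "shape": "disk",
                "nuclear_radius_um": control_radius_um,
                "body_radius_um": body_radius_um,
                "clearance_um": body_radius_um + 1.0,
            }
        )
    ctl_body = control_radius_um + dilation_um + 1.5
    for _ in range(n_control):
        specs.append(
            {
                "kind": "control",
                "shape": "disk",
                "nuclear_radius_um": control_radius_um,
                "body_radius_um": ctl_body,
                "clearance_um": ctl_body + 1.0,
            }
        )
    for r in offgate_radii_um:
        body = r + dilation_um + 1.5
        specs.append(
            {
                "kind": "control",
                "shape": "disk",
                "nuclear_radius_um": r,
                "body_radius_um": body,
                "clearance_um": body + 1.0,
            }
        )
    bar_size = (6, 95)  # px; area in-gate at 0.1625 um/px, circularity far below 0.9
    for _ in range(n_bars):
        half_diag = 0.5 * float(np.hypot(*bar_size)) * pixel_size_um
        specs.append(
            {
                "kind": "control",
                "shape": "bar",
                "nuclear_radius_um": 0.0,
                "body_radius_um": half_diag + dilation_um + 1.0,
                "clearance_um": half_diag + dilation_um + 2.0,
            }
        )

    placed: list[tuple[float, float, float]] = []  # (row, col, clearance_px)
    centers: list[tuple[float, float]] = []
    for spec in specs:
        clear_px = spec["clearance_um"] / pixel_size_um
        margin = clear_px + 2
        if 2 * margin >= min(image_shape):
            raise GenerationError("image too small for requested cell sizes")
        for attempt in range(5000):
            r = rng.uniform(margin, image_shape[0] - margin)
            c = rng.uniform(margin, image_shape[1] - margin)
            if all(
                np.hypot(r - pr, c - pc) > clear_px + pclear for pr, pc, pclear in placed
            ):
                placed.append((r, c, clear_px))
                centers.append((r, c))
                break
        else:
            raise GenerationError(
                f"could not place {len(specs)} non-overlapping cells in {image_shape}"
            )

    chans = {
        name: np.full(image_shape, background, dtype=float)
        for name in ("fl", "ecd", "nuclear")
    }
    cells: list[PlantedCell] = []
    for spec, center in zip(specs, centers):
        body_px = spec["body_radius_um"] / pixel_size_um
        nuc_px = spec["nuclear_radius_um"] / pixel_size_um
        if spec["shape"] == "bar":
            nuc = _bar_mask(image_shape, center, bar_size)
            body = nuc
        else:
            body = _disk_mask(image_shape, center, body_px)
            nuc = _disk_mask(image_shape, center, nuc_px)
        if spec["kind"] == "transfected":
            intensity = {"fl": fl_intensity, "ecd": ecd_transfected, "nuclear": nuclear_intensity}
            chans["fl"][body] = fl_intensity
            chans["ecd"][body] = ecd_transfected
            chans["nuclear"][nuc] = nuclear_intensity
        else:
            intensity = {"fl": background, "ecd": ecd_control, "nuclear": nuclear_intensity}
            chans["ecd"][body] = ecd_control
            chans["nuclear"][nuc] = nuclear_intensity
        cells.append(
            PlantedCell(
                kind=spec["kind"],
                center=center,
                nuclear_radius_um=spec["nuclear_radius_um"],
                body_radius_um=spec["body_radius_um"],
                intensity=intensity,
                shape=spec["shape"],
                bar_size_px=bar_size if spec["shape"] == "bar" else None,
            )
        )

    if noise_sd > 0:
        for name in chans:
            chans[name] = np.clip(
                chans[name] + rng.normal(0.0, noise_sd, size=image_shape), 0.0, None
            )
    if n_planes > 1:
        chans = {n: np.repeat(a[None], n_planes, axis=0) for n, a in chans.items()}

    stack = ImageStack(channels=chans, pixel_size_um=pixel_size_um)
    return stack, GroundTruth(cells=tuple(cells))


# --------------------------------------------------------------------------
# gradient images
# --------------------------------------------------------------------------

def gen_gradient_image(
    *,
    image_shape: tuple[int, int] = (200, 300),
    axis: str = "x",
    slope: float = 0.5,
    base: float = 10.0,
    channel_names: tuple[str, str] = ("Tenm", "Caps"),
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.31,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Two channels with opposing linear gradients along ``axis`` ("x" or "y")."""
    if axis not in ("x", "y"):
        raise ConfigurationError("axis must be 'x' or 'y'")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    length = w if axis == "x" else h
    coord = np.arange(length, dtype=float)
    up = base + slope * coord
    down = base + slope * (length - 1 - coord)
    if axis == "x":
        a = np.broadcast_to(up[None, :], image_shape).copy()
        b = np.broadcast_to(down[None, :], image_shape).copy()
    else:
        a = np.broadcast_to(up[:, None], image_shape).copy()
        b = np.broadcast_to(down[:, None], image_shape).copy()
    if noise_sd > 0:
        a = np.clip(a + rng.normal(0, noise_sd, image_shape), 0, None)
        b = np.clip(b + rng.normal(0, noise_sd, image_shape), 0, None)
    stack = ImageStack(
        channels={channel_names[0]: a, channel_names[1]: b},
        pixel_size_um=pixel_size_um,
    )
    truth = GroundTruth(gradient={"slope": slope, "base": base, "length": length, "axis": axis})
    return stack, truth


# --------------------------------------------------------------------------
# clone-scoring tables
# --------------------------------------------------------------------------

def gen_clone_table(
    genotypes: Sequence[tuple[str, int, float, Mapping[str, float]]],
    seed: int = 0,
) -> list["PenetranceRecord"]:
    """Binomial clone-scoring draws per genotype.

    ``genotypes`` holds (name, n_clones, true_penetrance, {glomerulus: p}).
    Mistargeted-clone totals are Binomial(n, penetrance); each glomerulus tally
    is Binomial(n_mistargeted, p), hence never exceeds the total.
    """
    from .stats import PenetranceRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    records = []
    for name, n_clones, pen, glom_probs in genotypes:
        if not (0.0 <= pen <= 1.0) or any(not 0.0 <= p <= 1.0 for p in glom_probs.values()):
            raise ConfigurationError("probabilities must be in [0, 1]")
        n_mis = int(rng.binomial(n_clones, pen))
        per_glom = {g: int(rng.binomial(n_mis, p)) for g, p in glom_probs.items()}
        records.append(
            PenetranceRecord(
                genotype=name, n_total=n_clones, n_mistargeted=n_mis, per_glomerulus=per_glom
            )
        )
    return records
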