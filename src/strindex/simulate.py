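"""Ground-truthed synthetic data: repeat distributions, traces, expression.

Three generators feed the rest of the package:

* :func:`simulate_somatic_distribution` builds an expansion-biased somatic
  repeat-length distribution — a point mass at the constitutive length, a
  geometric expansion tail, and a small contraction component — and the
  distribution's exact mean ΔCAG is recoverable from the returned object.
* :func:`render_trace` turns a distribution into a fragment-analyzer peak
  trace, convolving it with a minus-one-dominant geometric PCR stutter
  kernel, weighting by the amplification advantage of shorter alleles, and
  adding truncated Gaussian height noise.  With stutter, bias and noise all
  off, the instability index measured from the rendered trace equals the
  distribution's mean ΔCAG — an analytic identity the test suite relies on.
* :func:`simulate_expression` plants an instability-correlated probe
  signature into an otherwise null log2 expression matrix with replicate
  structure, for recovery scoring of the signature model and enrichment
  analyses.

``TISSUE_PRESETS`` defines a 17-"tissue" panel whose rendered instability
indices span roughly −1.0 (testis-like) to +6.4 (striatum-like), the range
observed across real mouse tissues; the tail preset is the stable
constitutive reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import RepeatLengthDistribution
from .traces import Peak, PeakTrace, write_peak_table

__all__ = [
    "TissueSimParams",
    "TraceRenderParams",
    "ExpressionSimParams",
    "TISSUE_PRESETS",
    "DEFAULT_MAIN_REPEATS",
    "simulate_somatic_distribution",
    "sample_molecules",
    "render_trace",
    "simulate_expression",
    "simulate_tissue_panel",
    "write_panel",
]

DEFAULT_MAIN_REPEATS = 111  # constitutive CAG count of the knock-in allele


@dataclass(frozen=True)
class TissueSimParams:
    """Shape of one tissue's somatic repeat-length distribution.

    ``expansion_rate`` is the expected ΔCAG gained per cell through the
    geometric expansion tail; ``contraction_mass`` the fraction of cells one
    or two repeats below the constitutive length; ``tail_shape`` the
    geometric decay of the expansion tail (larger → longer tail).
    """

    expansion_rate: float = 0.0
    contraction_mass: float = 0.0
    tail_shape: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_rate < 0:
            raise ValueError("expansion_rate must be non-negative")
        if not 0 <= self.contraction_mass < 1:
            raise ValueError("contraction_mass must lie in [0, 1)")
        if not 0 < self.tail_shape < 1:
            raise ValueError("tail_shape must lie in (0, 1)")


@dataclass(frozen=True)
class TraceRenderParams:
    """Instrument/PCR model for rendering a distribution as a peak trace."""

    stutter_ratio: float = 0.12
    plus_stutter: float = 0.0
    amp_bias: float = 0.03
    noise_sd: float = 20.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.stutter_ratio < 1:
            raise ValueError("stutter_ratio must lie in [0, 1)")
        if not 0 <= self.plus_stutter < 1:
            raise ValueError("plus_stutter must lie in [0, 1)")
        if self.amp_bias < 0:
            raise ValueError("amp_bias must be non-negative")
        if self.noise_sd < 0 or self.scale <= 0:
            raise ValueError("noise_sd must be ≥ 0 and scale > 0")


@dataclass(frozen=True)
class ExpressionSimParams:
    """Planted-signature expression simulation (log2 scale).

    ``seed`` fixes the planted structure (baselines, which probes carry the
    signature, their signs); ``noise_seed`` fixes the measurement noise and
    defaults to ``seed``.  Two cohorts sharing ``seed`` but differing in
    ``noise_seed`` are independent replicate arrays of the same underlying
    tissues — the natural train/test split.
    """

    n_tissues: int = 16
    n_probes: int = 20000
    n_signature_probes: int = 150
    n_replicates: int = 2
    effect_size: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_signature_probes > self.n_probes:
            raise ValueError("n_signature_probes must not exceed n_probes")
        if self.n_tissues < 3:
            raise ValueError("need at least 3 tissues")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")


# Contraction splits 3:1 over Δ = −1, −2.
_CONTRACTION_SPLIT = {-1: 0.75, -2: 0.25}


def simulate_somatic_distribution(
    params: TissueSimParams,
    main_repeats: int = DEFAULT_MAIN_REPEATS,
) -> RepeatLengthDistribution:
    """Exact mixture distribution of somatic repeat lengths for one tissue.

    Mass ``contraction_mass`` sits at Δ ∈ {−1, −2} (3:1), a geometric tail
    over Δ ≥ 1 carries expected gain ``expansion_rate``, and the remainder
    stays at Δ = 0.  The construction is closed-form (the seed only matters
    when molecules are sampled from it), and the returned object's
    ``mean_delta()`` is the exact generating mean.
    """
    q = params.tail_shape
    c = params.contraction_mass
    tail_mass = params.expansion_rate * (1 - q)  # tail mean is 1/(1-q)
    if tail_mass + c > 1:
        raise ValueError(
            f"infeasible parameters: expansion tail mass {tail_mass:.3f} + "
            f"contraction mass {c:.3f} exceeds 1"
        )
    freqs: dict[int, float] = {0: 1.0 - tail_mass - c}
    for delta, frac in _CONTRACTION_SPLIT.items():
        if c > 0:
            freqs[delta] = c * frac
    if tail_mass > 0:
        # truncate where the residual tail is numerically negligible and
        # fold the remainder into the last rung to conserve mass
        k_max = max(2, math.ceil(math.log(1e-14) / math.log(q)))
        for k in range(1, k_max):
            freqs[k] = tail_mass * (1 - q) * q ** (k - 1)
        freqs[k_max] = tail_mass * q ** (k_max - 1)
    counts = {main_repeats + d: f for d, f in freqs.items() if f > 0}
    return RepeatLengthDistribution(counts=counts, main_repeats=main_repeats)


def sample_molecules(
    dist: RepeatLengthDistribution, n_molecules: int, seed: int = 0
) -> RepeatLengthDistribution:
    """Draw a finite molecule sample (multinomial), as small-pool PCR would."""
    rng = np.random.default_rng(seed)
    lengths = dist.lengths
    probs = np.array(list(dist.frequencies().values()))
    drawn = rng.multinomial(n_molecules, probs)
    counts = {int(l): int(n) for l, n in zip(lengths, drawn) if n > 0}
    return RepeatLengthDistribution(counts=counts, main_repeats=dist.main_repeats)


def _stutter_kernel(stutter_ratio: float, plus_stutter: float) -> dict[int, float]:
    """Geometric minus-k slippage kernel plus optional +1 component; sums to 1."""
    s = stutter_ratio
    kernel = {}
    if plus_stutter > 0:
        kernel[1] = plus_stutter
    if s == 0:
        kernel[0] = 1.0 - plus_stutter
        return kernel
    k_max = max(1, math.ceil(math.log(1e-12) / math.log(s)))
    for k in range(k_max):
        kernel[-k] = (1.0 - plus_stutter) * (1 - s) * s**k
    kernel[-k_max] = (1.0 - plus_stutter) * s**k_max
    return kernel


_BASE_SIGNAL_RFU = 8000.0  # tallest-trace total before scaling
_FLANK_BP = 100.0  # non-repeat flank carried by the amplicon


def render_trace(
    dist: RepeatLengthDistribution,
    params: TraceRenderParams = TraceRenderParams(),
    sample_id: str = "sim",
    tissue: str = "",
    unit_spacing: float = 3.0,
) -> PeakTrace:
    """Render a repeat-length distribution as a fragment peak trace.

    heights ∝ (distribution ∗ stutter kernel) × (1 + amp_bias)^(−Δ), scaled
    to a total of ``scale`` × 8000 RFU, with Gaussian height noise truncated
    at zero; fragment sizes sit at exact ``unit_spacing`` multiples.
    """
    anchor = dist.main_repeats if dist.main_repeats is not None else dist.modal_length()
    kernel = _stutter_kernel(params.stutter_ratio, params.plus_stutter)
    signal: dict[int, float] = {}
    for length, freq in dist.frequencies().items():
        for shift, mass in kernel.items():
            out = length + shift
            signal[out] = signal.get(out, 0.0) + freq * mass
    lengths = np.array(sorted(signal), dtype=int)
    heights = np.array([signal[l] for l in lengths])
    heights = heights * (1.0 + params.amp_bias) ** (-(lengths - anchor))
    heights = heights / heights.sum() * _BASE_SIGNAL_RFU * params.scale
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        heights = np.clip(heights + rng.normal(0.0, params.noise_sd, heights.size), 0.0, None)
    sizes = _FLANK_BP + unit_spacing * lengths
    peaks = tuple(Peak(float(s), float(h)) for s, h in zip(sizes, heights) if h > 0)
    return PeakTrace(sample_id=sample_id, tissue=tissue, peaks=peaks)


def main_allele_size(
    main_repeats: int = DEFAULT_MAIN_REPEATS, unit_spacing: float = 3.0
) -> float:
    """Fragment size (bp) at which the constitutive allele renders."""
    return _FLANK_BP + unit_spacing * main_repeats


# Panel of tissue-like presets.  expansion_rate / contraction_mass were
# calibrated once so that default noise-free renders (stutter 0.12, bias
# 0.03, threshold 0.20) yield instability indices spanning the range
# observed across mouse tissues, ~−1.0 (testis-like) to +6.4
# (striatum-like), with the tail as stable reference.
TISSUE_PRESETS: dict[str, TissueSimParams] = {
    "tail": TissueSimParams(expansion_rate=0.0, contraction_mass=0.0, tail_shape=0.6),
    "striatum": TissueSimParams(expansion_rate=15.7164, contraction_mass=0.02, tail_shape=0.94),
    "liver": TissueSimParams(expansion_rate=18.2885, contraction_mass=0.02, tail_shape=0.95),
    "kidney": TissueSimParams(expansion_rate=1.8922, contraction_mass=0.03, tail_shape=0.6),
    "cortex": TissueSimParams(expansion_rate=1.6153, contraction_mass=0.03, tail_shape=0.6),
    "cerebellum": TissueSimParams(expansion_rate=1.5825, contraction_mass=0.03, tail_shape=0.6),
    "stomach": TissueSimParams(expansion_rate=1.9098, contraction_mass=0.03, tail_shape=0.7),
    "skin": TissueSimParams(expansion_rate=1.1166, contraction_mass=0.03, tail_shape=0.6),
    "pancreas": TissueSimParams(expansion_rate=0.9253, contraction_mass=0.03, tail_shape=0.6),
    "hippocampus": TissueSimParams(expansion_rate=0.8502, contraction_mass=0.03, tail_shape=0.6),
    "spleen": TissueSimParams(expansion_rate=0.02, contraction_mass=0.2263, tail_shape=0.6),
    "small_intestine": TissueSimParams(expansion_rate=0.02, contraction_mass=0.2673, tail_shape=0.6),
    "ovary": TissueSimParams(expansion_rate=0.02, contraction_mass=0.3364, tail_shape=0.6),
    "large_intestine": TissueSimParams(expansion_rate=0.02, contraction_mass=0.4495, tail_shape=0.6),
    "lung": TissueSimParams(expansion_rate=0.02, contraction_mass=0.5756, tail_shape=0.6),
    "heart": TissueSimParams(expansion_rate=0.02, contraction_mass=0.7348, tail_shape=0.6),
    "testis": TissueSimParams(expansion_rate=0.02, contraction_mass=0.7518, tail_shape=0.6),
}


def simulate_tissue_panel(
    render_params: TraceRenderParams = TraceRenderParams(),
    tissues: list[str] | None = None,
    main_repeats: int = DEFAULT_MAIN_REPEATS,
    seed: int = 0,
) -> tuple[dict[str, PeakTrace], dict[str, dict]]:
    """Render one trace per preset tissue; returns (traces, truth).

    ``truth[tissue]`` records the generating parameters and the exact mean
    ΔCAG of the underlying distribution.  Per-tissue render seeds derive
    from ``seed`` so panels are reproducible as a whole.
    """
    names = list(TISSUE_PRESETS) if tissues is None else tissues
    traces: dict[str, PeakTrace] = {}
    truth: dict[str, dict] = {}
    for i, name in enumerate(names):
        params = TISSUE_PRESETS[name]
        dist = simulate_somatic_distribution(params, main_repeats=main_repeats)
        rp = TraceRenderParams(
            stutter_ratio=render_params.stutter_ratio,
            plus_stutter=render_params.plus_stutter,
            amp_bias=render_params.amp_bias,
            noise_sd=render_params.noise_sd,
            scale=render_params.scale,
            seed=(seed * 1009 + i) % (2**31),
        )
        traces[name] = render_trace(dist, rp, sample_id=f"{name}_s1", tissue=name)
        truth[name] = {
            "params": asdict(params),
            "true_mean_delta": dist.mean_delta(),
            "main_repeats": main_repeats,
        }
    return traces, truth


def write_panel(
    out_dir: str | Path,
    render_params: TraceRenderParams = TraceRenderParams(),
    main_repeats: int = DEFAULT_MAIN_REPEATS,
    seed: int = 0,
) -> Path:
    """Write a full panel dataset: peak CSVs, a manifest, and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, truth = simulate_tissue_panel(render_params, main_repeats=main_repeats, seed=seed)
    rows = []
    for name, trace in traces.items():
        fname = f"{name}.csv"
        write_peak_table(trace, out / fname)
        rows.append({
            "sample_id": trace.sample_id,
            "tissue": name,
            "role": "tail" if name == "tail" else "tissue",
            "path": fname,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump({"seed": seed, "render": asdict(render_params), "tissues": truth}, fh, indent=1)
    return manifest


def simulate_expression(
    params: ExpressionSimParams,
    true_index: dict[str, float] | None = None,
):
    """Planted-signature log2 expression matrix with replicate structure.

    Signature probes respond to the tissue's true instability index with
    slope ±``effect_size`` (random sign per probe); decoy probes are pure
    noise around their baselines.  Replicate samples of a tissue share its
    phenotype value.  Returns ``(ExpressionMatrix, truth)`` where ``truth``
    lists the planted probe ids, their signs, and the per-tissue index.
    """
    from .signature import ExpressionMatrix  # local import avoids a cycle

    rng = np.random.default_rng(params.seed)
    # a decoupled stream, so cohorts sharing `seed` differ only in noise
    eff = params.seed if params.noise_seed is None else params.noise_seed
    noise_rng = np.random.default_rng([eff, 1])
    if true_index is None:
        non_tail = [t for t in TISSUE_PRESETS if t != "tail"]
        names = non_tail[: params.n_tissues]
        if len(names) < params.n_tissues:
            names += [f"tissue_{i}" for i in range(len(names), params.n_tissues)]
        true_index = {
            name: simulate_somatic_distribution(
                TISSUE_PRESETS.get(name, TissueSimParams(expansion_rate=rng.uniform(0, 3)))
            ).mean_delta()
            for name in names
        }
    tissues = list(true_index)[: params.n_tissues]
    if len(tissues) < params.n_tissues:
        raise ValueError("true_index supplies fewer tissues than n_tissues")

    digits = max(5, len(str(params.n_probes - 1)))
    probe_ids = [f"P{i:0{digits}d}" for i in range(params.n_probes)]
    sig_idx = np.sort(rng.choice(params.n_probes, size=params.n_signature_probes, replace=False))
    signs = rng.choice([-1.0, 1.0], size=params.n_signature_probes)

    sample_ids, tissue_of, pheno = [], [], []
    for t in tissues:
        for r in range(1, params.n_replicates + 1):
            sample_ids.append(f"{t}_r{r}")
            tissue_of.append(t)
            pheno.append(true_index[t])
    pheno_arr = np.asarray(pheno)

    baseline = rng.normal(7.0, 1.0, size=params.n_probes)
    values = baseline[:, None] + noise_rng.normal(
        0.0, params.noise_sd, size=(params.n_probes, len(sample_ids))
    )
    values[sig_idx, :] += (signs * params.effect_size)[:, None] * pheno_arr[None, :]

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        phenotype=pd.Series(pheno_arr, index=sample_ids, name="instability_index"),
        tissue_of=pd.Series(tissue_of, index=sample_ids, name="tissue"),
    )
    truth = {
        "signature_probes": [probe_ids[i] for i in sig_idx],
        "signs": {probe_ids[i]: float(s) for i, s in zip(sig_idx, signs)},
        "true_index": {t: float(v) for t, v in true_index.items() if t in tissues},
        "effect_size": params.effect_size,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
    }
    return expr, truth
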