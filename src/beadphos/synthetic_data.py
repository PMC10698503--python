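"""Simulators with planted ground truth for every pipeline input.

Three generators emulate the study conditions of a two-phosphatase
specificity screen:

- :func:`simulate_dephos` — encoded-bead dephosphorylation time courses:
  per-bead lognormal starting amplitudes, single-exponential decay with
  peptide-specific rates composed from design attributes (acceptor, +1 Pro,
  upstream basic content), a phosphate-free negative-control code, and a
  fraction of failed-synthesis codes whose signal tracks the control.
- :func:`simulate_binding` — Langmuir titration curves for an RVxF variant
  panel; per-variant K_d truths are composed from a reference K_d and planted
  per-substitution ΔΔG values.
- :func:`simulate_phosphoproteome` — a two-arm (PP1 / B55) inhibitor-vs-
  control TMT phosphosite table with planted regulated fractions, effect
  sizes and class-specific sequence signatures, a protein FASTA consistent
  with the site windows, a label-free interactor table with
  intensity-dependent missingness, and one long unstructured protein with a
  single RVxF motif for near/far stratification.

All randomness flows through one ``numpy`` generator per call: a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace as dc_replace

import numpy as np
import pandas as pd

from . import library_design as ld
from .bead_quant import CodeTable
from .binding_affinity import DEFAULT_CONC_GRID, kd_from_ddg, langmuir
from .dephos_scoring import DEFAULT_TIME_GRID
from .errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Reference peptide of the RVxF variant panel (motif core at 5-8).
RVXF_REFERENCE = "AKNSRVTFSEDDEII"
RVXF_MOTIF_START = 5


@dataclass
class RateModel:
    """Multiplicative dephosphorylation-rate model over design attributes."""

    base_rate: float = 0.01           # 1/min for pS, no +1 Pro, neutral flanks
    pt_multiplier: float = 3.0        # pThr dephosphorylated faster than pSer
    plus1_pro_multiplier: float = 0.3 # +1 proline slows dephosphorylation
    basic_upstream_multiplier: float = 1.5   # per K/R at -2/-3
    acidic_plus2_multiplier: float = 0.5

    def rate_for(self, peptide: ld.PhosphoPeptide) -> float:
        if not peptide.is_phosphorylated:
            return 0.0
        k = self.base_rate
        if peptide.acceptor == "pT":
            k *= self.pt_multiplier
        if peptide.plus1_residue == "P":
            k *= self.plus1_pro_multiplier
        (pos,) = peptide.phospho_positions
        for off in (2, 3):
            if pos - off >= 1 and peptide.sequence[pos - off - 1] in "KR":
                k *= self.basic_upstream_multiplier
        if pos + 2 <= len(peptide.sequence) and peptide.sequence[pos + 1] in "DE":
            # +2 relative means two residues C-terminal; index pos+1 is +2 slot
            k *= self.acidic_plus2_multiplier
        return k


@dataclass
class SimConfig:
    """Shared knobs of the three simulators (defaults = study conditions)."""

    seed: int = 0
    # bead assays
    n_codes: int = 95
    beads_per_code: float = 55.0
    n_replicates: int = 3
    n_lanthanide_channels: int = 4
    code_jitter_frac: float = 0.02    # bead-vector jitter, fraction of code spacing
    amplitude_mu_log: float = float(np.log(1000.0))
    amplitude_sigma_log: float = 0.25
    background: float = 100.0
    noise_cv: float = 0.05
    noise_additive_sd: float = 2.0
    failed_code_fraction: float = 0.05
    time_grid: tuple = DEFAULT_TIME_GRID
    rate_model: RateModel = field(default_factory=RateModel)
    # binding
    conc_grid: tuple = DEFAULT_CONC_GRID
    y_max: float = 15000.0
    kd_reference: float = 125.0
    binding_noise_frac: float = 0.03
    binding_beads_per_code: float = 35.0
    # phosphoproteome
    n_sites: int = 5000
    frac_pp1: float = 0.10
    frac_b55: float = 0.20
    frac_both: float = 0.02
    effect_mean: float = 1.5
    effect_sd: float = 0.2
    effect_min: float = 0.8
    replicate_noise_sd: float = 0.15
    flank: int = 7
    sites_per_protein: int = 10
    interactor_fraction: float = 0.05
    interactor_log2_effect: float = 2.0
    interactor_noise_sd: float = 0.5
    n_lf_proteins: int = 600
    lf_missing_max: float = 0.25      # missingness at the low-intensity end

    def __post_init__(self):
        for frac in (self.failed_code_fraction, self.frac_pp1, self.frac_b55,
                     self.frac_both, self.interactor_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"fraction {frac} outside [0, 1]")
        for grid in (self.time_grid, self.conc_grid):
            if not all(b > a for a, b in zip(grid, grid[1:])):
                raise ConfigurationError("grids must be strictly increasing")


@dataclass
class GroundTruth:
    """Planted truths keyed the same way as the emitted tables."""

    rates: dict = field(default_factory=dict)           # peptide_id -> k (1/min)
    kds: dict = field(default_factory=dict)             # peptide_id -> K_d (nM)
    ddg_cells: dict = field(default_factory=dict)       # "pos:res" -> ΔΔG
    failed_codes: list = field(default_factory=list)
    negative_control_code: str = ""
    site_class: dict = field(default_factory=dict)      # site_id -> class
    site_effect: dict = field(default_factory=dict)     # site_id -> (arm effects)
    interactors: dict = field(default_factory=dict)     # protein_id -> bool
    motif_groups: dict = field(default_factory=dict)    # site_id -> near/far
    y_max: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def make_code_table(n_codes: int, n_channels: int = 4, negative_control_code=None) -> CodeTable:
    """Deterministic grid of distinct ratio vectors (unit-interval levels)."""
    n_levels = int(np.ceil(n_codes ** (1.0 / n_channels)))
    n_levels = max(n_levels, 2)
    levels = np.linspace(0.1, 1.0, n_levels)
    combos = list(itertools.product(levels, repeat=n_channels))[:n_codes]
    if len(combos) < n_codes:
        raise ConfigurationError("not enough grid points for requested codes")
    codes = {f"code{i + 1:03d}": np.asarray(v) for i, v in enumerate(combos)}
    return CodeTable(codes=codes, negative_control_code=negative_control_code)


def _bead_rows(rng, code_vec, jitter_sd, n_channels):
    return code_vec + rng.normal(0.0, jitter_sd, n_channels)


def simulate_dephos(config: SimConfig):
    """Simulate a dephosphorylation bead experiment.

    Returns ``(bead_table, truth, library, code_table)``.  The bead table has
    columns bead_id, l1..lL, intensity, condition (min), replicate_id,
    sample_id, and decodes/scores through the standard pipeline.
    """
    rng = np.random.default_rng(config.seed)
    n_pep = config.n_codes - 1
    library = ld.build_dephos_panel(n_pep, control=True)
    control = library[-1]
    code_table = make_code_table(
        config.n_codes, config.n_lanthanide_channels,
        negative_control_code=control.code_id,
    )
    jitter_sd = config.code_jitter_frac * code_table.min_spacing()

    n_fail = int(round(config.failed_code_fraction * n_pep))
    failed = sorted(rng.choice([p.code_id for p in library[:-1]], size=n_fail, replace=False))
    failed_set = set(failed)

    truth = GroundTruth(
        failed_codes=list(failed),
        negative_control_code=control.code_id,
    )
    times = np.asarray(config.time_grid, dtype=float)

    rows = []
    bead_counter = itertools.count(1)
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        for pep in library:
            k = config.rate_model.rate_for(pep)
            if pep.is_phosphorylated and pep.code_id not in failed_set:
                truth.rates[pep.peptide_id] = k
            n_beads = max(1, rng.poisson(config.beads_per_code))
            vec = code_table.codes[pep.code_id]
            for _ in range(n_beads):
                bead_id = f"bead{next(bead_counter):06d}"
                lvec = _bead_rows(rng, vec, jitter_sd, config.n_lanthanide_channels)
                if (not pep.is_phosphorylated) or pep.code_id in failed_set:
                    clean = np.full_like(times, config.background)
                else:
                    amp = rng.lognormal(config.amplitude_mu_log, config.amplitude_sigma_log)
                    clean = config.background + amp * np.exp(-k * times)
                noisy = clean * (1.0 + config.noise_cv * rng.normal(size=times.size))
                noisy = noisy + rng.normal(0.0, config.noise_additive_sd, times.size)
                noisy = np.clip(noisy, 0.0, None)
                for t, y in zip(times, noisy):
                    rows.append(
                        (bead_id, *lvec, float(y), float(t), rep_id, "dephos_sim")
                    )
    lcols = [f"l{i + 1}" for i in range(config.n_lanthanide_channels)]
    beads = pd.DataFrame(
        rows, columns=["bead_id", *lcols, "intensity", "condition", "replicate_id", "sample_id"]
    )
    return beads, truth, library, code_table


# ---------------------------------------------------------------------------
# Binding panel
# ---------------------------------------------------------------------------

def build_rvxf_panel(rng: np.random.Generator):
    """RVxF substitution panel around :data:`RVXF_REFERENCE` with planted ΔΔGs.

    Single substitutions at positions 4-10 to a handful of residues, plus
    phospho-variants at position 4 (pSer -1 of core), 7 (pThr inside the
    core) and 9 (pSer +1 of core).  Planted ΔΔG values are drawn once from
    Uniform(-0.5, 2.0) kcal/mol, except prolines inside the core, which are
    strongly disfavored (+2.2 to +2.8).  Returns
    ``(peptides, annotations, ddg_cells)``.
    """
    core = set(range(RVXF_MOTIF_START, RVXF_MOTIF_START + 4))  # 5..8
    sub_residues = {pos: [r for r in "AEKPG" if r != RVXF_REFERENCE[pos - 1]]
                    for pos in range(4, 11)}
    phospho_cells = [(4, "s"), (7, "t"), (9, "s")]

    peptides = []
    annotations = {}
    ddg_cells = {}
    idx = 1

    def add(pos, res, ddg):
        nonlocal idx
        seq = RVXF_REFERENCE[: pos - 1] + res + RVXF_REFERENCE[pos:]
        pid = f"rv{idx:03d}"
        plain, ppos = ld.parse_sequence(seq)
        pep = ld.PhosphoPeptide(
            peptide_id=pid, sequence=plain, phospho_positions=ppos,
            code_id=f"code{idx:03d}",
        )
        peptides.append(pep)
        annotations[pid] = (pos, res)
        ddg_cells[f"{pos}:{res}"] = float(ddg)
        idx += 1

    ref = ld.PhosphoPeptide(
        peptide_id="ref", sequence=RVXF_REFERENCE, phospho_positions=frozenset(),
        code_id="code000",
    )
    peptides.append(ref)
    for pos in sorted(sub_residues):
        for res in sub_residues[pos]:
            if res == "P" and pos in core:
                ddg = rng.uniform(2.2, 2.8)
            else:
                ddg = rng.uniform(-0.5, 2.0)
            add(pos, res, ddg)
    for pos, res in phospho_cells:
        add(pos, res, rng.uniform(1.5, 2.2))
    return peptides, annotations, ddg_cells


def simulate_binding(config: SimConfig):
    """Simulate an RVxF-panel titration experiment.

    Returns ``(bead_table, truth, peptides, annotations, code_table)``.  The
    bead table's ``condition`` column is the titrant concentration in nM.
    """
    rng = np.random.default_rng(config.seed)
    peptides, annotations, ddg_cells = build_rvxf_panel(rng)
    code_table = make_code_table(len(peptides), config.n_lanthanide_channels)
    ids = list(code_table.codes)
    peptides = [dc_replace(p, code_id=cid) for p, cid in zip(peptides, ids)]
    code_of = {p.peptide_id: p.code_id for p in peptides}
    jitter_sd = config.code_jitter_frac * code_table.min_spacing()

    truth = GroundTruth(ddg_cells=ddg_cells, y_max=config.y_max)
    truth.kds["ref"] = config.kd_reference
    for pid, (pos, res) in annotations.items():
        truth.kds[pid] = kd_from_ddg(ddg_cells[f"{pos}:{res}"], config.kd_reference)

    conc = np.asarray(config.conc_grid, dtype=float)
    noise_sd = config.binding_noise_frac * config.y_max
    rows = []
    bead_counter = itertools.count(1)
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        for pep in peptides:
            kd = truth.kds[pep.peptide_id]
            clean = langmuir(conc, config.y_max, kd)
            n_beads = max(1, rng.poisson(config.binding_beads_per_code))
            vec = code_table.codes[code_of[pep.peptide_id]]
            for _ in range(n_beads):
                bead_id = f"bead{next(bead_counter):06d}"
                lvec = _bead_rows(rng, vec, jitter_sd, config.n_lanthanide_channels)
                noisy = np.clip(clean + rng.normal(0.0, noise_sd, conc.size), 0.0, None)
                for c, y in zip(conc, noisy):
                    rows.append((bead_id, *lvec, float(y), float(c), rep_id, "binding_sim"))
    lcols = [f"l{i + 1}" for i in range(config.n_lanthanide_channels)]
    beads = pd.DataFrame(
        rows, columns=["bead_id", *lcols, "intensity", "condition", "replicate_id", "sample_id"]
    )
    return beads, truth, peptides, annotations, code_table


# ---------------------------------------------------------------------------
# Phosphoproteome
# ---------------------------------------------------------------------------

_BASIC = "KR"
_ACIDIC = "DE"

#: Long synthetic substrate used for near/far motif stratification.
LONG_PROTEIN_ID = "SYNLONG1"
LONG_PROTEIN_LENGTH = 3256
LONG_MOTIF_START = 504  # "RAVTF" planted at 504-508 (RxVxF register)


def _draw_residue(rng, exclude=""):
    pool = [a for a in AMINO_ACIDS if a not in exclude]
    return pool[rng.integers(len(pool))]


def _make_window(rng, cls: str, flank: int) -> str:
    """One centered window with the class's positional signature."""
    width = 2 * flank + 1
    chars = [_draw_residue(rng, exclude="XSTY") for _ in range(width)]
    c = flank  # center index
    if cls == "PP1":
        chars[c] = "S" if rng.random() < 0.58 else "T"
        for off in (2, 3):  # basic residues at -2/-3
            if rng.random() < 0.40:
                chars[c - off] = _BASIC[rng.integers(2)]
        if chars[c] == "S" and chars[c + 1] == "P":
            chars[c + 1] = "A"  # pSer +1 Pro deselected
    elif cls in ("B55", "ambiguous"):
        chars[c] = "S" if rng.random() < 0.65 else "T"
        if rng.random() < 0.50:
            chars[c + 1] = "P"  # proline-directed preference
        if chars[c + 2] in _ACIDIC:
            chars[c + 2] = "G"  # acidic +2 deselected
    else:
        chars[c] = "S" if rng.random() < 0.70 else "T"
        for off in (2, 3):
            if rng.random() < 0.10:
                chars[c - off] = _BASIC[rng.integers(2)]
        if rng.random() < 0.05:
            chars[c + 1] = "P"
    return "".join(chars)


def simulate_phosphoproteome(config: SimConfig):
    """Simulate the two-arm TMT phosphosite screen plus interactome inputs.

    Returns ``(sites, proteins, lf_table, truth)``:

    - ``sites``: wide site table (site_id, protein_id, position, acceptor,
      window, and ``{arm}_{group}_r{i}`` log2 intensity columns).
    - ``proteins``: dict protein_id -> sequence consistent with the windows,
      including one long protein with a single RVxF motif and a planted
      near/far composition contrast.
    - ``lf_table``: label-free log2 intensities (bait/ctrl triplicates) with
      intensity-dependent missingness, indexed by protein_id.
    - ``truth``: planted classes, effects, interactor flags, motif groups.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    flank = config.flank
    truth = GroundTruth()

    # -- classes ------------------------------------------------------------
    n_pp1 = int(round(config.frac_pp1 * n))
    n_b55 = int(round(config.frac_b55 * n))
    n_both = int(round(config.frac_both * n))
    classes = (["PP1"] * n_pp1 + ["B55"] * n_b55 + ["ambiguous"] * n_both
               + ["unregulated"] * (n - n_pp1 - n_b55 - n_both))
    rng.shuffle(classes)

    windows = [_make_window(rng, cls, flank) for cls in classes]
    site_ids = [f"site{i + 1:05d}" for i in range(n)]

    # -- intensities ---------------------------------------------------------
    def effect():
        return max(config.effect_min, rng.normal(config.effect_mean, config.effect_sd))

    base = rng.normal(20.0, 1.0, n)
    cols = {}
    eff_pp1 = np.zeros(n)
    eff_b55 = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls in ("PP1", "ambiguous"):
            eff_pp1[i] = effect()
        if cls in ("B55", "ambiguous"):
            eff_b55[i] = effect()
    for arm, eff in (("pp1", eff_pp1), ("b55", eff_b55)):
        for r in range(1, 4):
            cols[f"{arm}_ctrl_r{r}"] = base + rng.normal(0, config.replicate_noise_sd, n)
            cols[f"{arm}_inhib_r{r}"] = base + eff + rng.normal(0, config.replicate_noise_sd, n)

    # -- proteins hosting the windows ----------------------------------------
    proteins: dict = {}
    protein_ids = []
    positions = []
    per_prot = config.sites_per_protein
    i = 0
    prot_idx = 0
    while i < n:
        prot_idx += 1
        pid = f"SYNP{prot_idx:04d}"
        chunk = range(i, min(i + per_prot, n))
        seq_parts = []
        pos_cursor = 0
        for j in chunk:
            linker_len = int(rng.integers(10, 30))
            linker = "".join(_draw_residue(rng, exclude="STY") for _ in range(linker_len))
            seq_parts.append(linker)
            pos_cursor += linker_len
            seq_parts.append(windows[j])
            positions.append(pos_cursor + flank + 1)
            protein_ids.append(pid)
            pos_cursor += len(windows[j])
        proteins[pid] = "".join(seq_parts)
        i += per_prot

    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "protein_id": protein_ids,
            "position": positions,
            "acceptor": [w[flank] for w in windows],
            "localized": True,
            "multiplicity": "single",
            "unique_protein_match": True,
            "window": windows,
            **cols,
        }
    )
    truth.site_class = dict(zip(site_ids, classes))
    truth.site_effect = {
        sid: {"pp1": float(a), "b55": float(b)}
        for sid, a, b in zip(site_ids, eff_pp1, eff_b55)
    }

    # -- long protein with one RVxF motif and a near/far contrast -------------
    # Alphabet without F/W so the only aromatic-slot match is the planted one.
    def _bg(nres):
        return "".join(_draw_residue(rng, exclude="STYFW") for _ in range(nres))

    long_seq = list(_bg(LONG_PROTEIN_LENGTH))
    long_seq[LONG_MOTIF_START - 1 : LONG_MOTIF_START + 4] = list("RAVTF")
    # sites spaced >= 12 residues apart so flank edits never hit another center
    near_pool = [p for p in range(50, 950, 12)
                 if not LONG_MOTIF_START - 12 <= p <= LONG_MOTIF_START + 12]
    near_positions = sorted(rng.choice(np.asarray(near_pool), size=40, replace=False))
    far_positions = sorted(
        rng.choice(np.arange(1100, LONG_PROTEIN_LENGTH - 50, 12), size=60, replace=False)
    )
    long_rows = []
    for grp, pos_list in (("near", near_positions), ("far", far_positions)):
        for p in pos_list:
            p = int(p)
            if grp == "near":
                long_seq[p - 1] = "S"
                for off in (2, 3):
                    if rng.random() < 0.6:
                        long_seq[p - 1 - off] = _BASIC[rng.integers(2)]
            else:
                long_seq[p - 1] = "T"
                if rng.random() < 0.7:
                    long_seq[p] = "P"
            sid = f"long{p:05d}"
            truth.motif_groups[sid] = grp
            long_rows.append((sid, p))
    proteins[LONG_PROTEIN_ID] = "".join(long_seq)
    long_sites = pd.DataFrame(
        {
            "site_id": [sid for sid, _ in long_rows],
            "protein_id": LONG_PROTEIN_ID,
            "position": [p for _, p in long_rows],
        }
    )

    # -- label-free interactor table ------------------------------------------
    site_prots = sorted(set(protein_ids))
    extra = [f"SYNX{i + 1:04d}" for i in range(max(0, config.n_lf_proteins - len(site_prots)))]
    lf_prots = (site_prots + extra)[: config.n_lf_proteins]
    n_lf = len(lf_prots)
    n_int = int(round(config.interactor_fraction * n_lf))
    int_flags = np.zeros(n_lf, dtype=bool)
    int_flags[rng.choice(n_lf, size=n_int, replace=False)] = True
    lf_base = rng.normal(25.0, 2.0, n_lf)
    lf = {}
    for r in range(1, 4):
        lf[f"ctrl_r{r}"] = lf_base + rng.normal(0, config.interactor_noise_sd, n_lf)
        lf[f"bait_r{r}"] = (
            lf_base
            + np.where(int_flags, config.interactor_log2_effect, 0.0)
            + rng.normal(0, config.interactor_noise_sd, n_lf)
        )
    lf_table = pd.DataFrame(lf, index=pd.Index(lf_prots, name="protein_id"))
    # intensity-dependent (MNAR) missingness: logistic in the true intensity
    if config.lf_missing_max > 0:
        for col in lf_table.columns:
            v = lf_table[col].to_numpy()
            pmiss = config.lf_missing_max / (1.0 + np.exp((v - (lf_base.mean() - 2.5))))
            mask = rng.random(n_lf) < pmiss
            lf_table.loc[mask, col] = np.nan
    truth.interactors = dict(zip(lf_prots, (bool(f) for f in int_flags)))

    return sites, proteins, lf_table, truth, long_sites


def write_fasta(proteins: dict, path) -> None:
    """Write protein sequences as uncompressed FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for pid in proteins:
            fh.write(f">{pid}\n")
            seq = proteins[pid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
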