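"""GWAS case-control simulation on synthetic haplotype panels.

The engine mirrors a standard two-stage association design:

1. a large phased haplotype panel (the "population") with a skewed
   minor-allele-frequency spectrum and LD that decays with inter-SNP distance;
2. a designated causal SNP and disease model; cases are sampled by first
   drawing the causal genotype with probabilities proportional to
   ((1-f)^2, 2f(1-f)*alpha1, f^2*alpha2) and then drawing consistent haplotype
   pairs uniformly without replacement, controls are uniform haplotype pairs
   (an unphenotyped cohort);
3. a trend-test scan over the SNPs on a genotyping "chip" (a thinned SNP
   subset); the smallest-p chip SNP is the *hit* SNP and must reach the scan
   threshold; a replication sample at the hit SNP must reach the replication
   threshold; finally a deviation test on the replication counts checks for
   departure from the multiplicative model.

Each study therefore ends in one of three outcomes: undetected, association
only, or association plus deviation.

The panel generator is a first-order mosaic: panel haplotypes copy from a
small pool of founder haplotypes, switching founder with a distance-dependent
probability; founders themselves follow a Markov chain along SNPs so nearby
founder columns are correlated.  This gives seedable panels with tunable r^2
decay; it does not model recombination hotspots, gene conversion or
population structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import deviation_stats, trend_stats
from .models import GeneralModel

__all__ = [
    "HaplotypePanel",
    "StudyOutcome",
    "generate_panel",
    "sample_cases_controls",
    "run_study",
    "run_experiment",
    "aggregate_outcomes",
    "outcome_by_ld_bins",
    "write_panel",
    "read_panel",
    "pairwise_r2",
    "DEFAULT_THRESHOLDS",
]

#: scan, replication and deviation significance thresholds
DEFAULT_THRESHOLDS = (1e-6, 0.01, 0.05)

OUTCOMES = ("undetected", "assoc_only", "assoc_plus_deviation")


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix with positions and a chip mask.

    haplotypes has shape (n_hap, n_snp) with n_hap even; chip_mask marks the
    SNPs available to the scan (the genotyping chip).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chip_mask: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] % 2 != 0 or h.shape[0] < 2:
            raise ValueError("haplotypes must be (n_hap, n_snp) with even n_hap >= 2")
        if np.any(h > 1):
            raise ValueError("alleles must be coded 0/1")
        self.haplotypes = h
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chip_mask = np.asarray(self.chip_mask, dtype=bool)
        if self.positions.shape != (h.shape[1],) or self.chip_mask.shape != (
            h.shape[1],
        ):
            raise ValueError("positions and chip_mask must have one entry per SNP")
        if not self.chip_mask.any():
            raise ValueError("chip mask must retain at least one SNP")
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(h.shape[1])]

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Allele-1 frequency per SNP (column means)."""
        return self.haplotypes.mean(axis=0)


def generate_panel(
    n_hap: int = 100_000,
    n_snp: int = 1000,
    region_bp: int = 500_000,
    maf_spec: tuple[float, float] = (0.6, 1.8),
    ld_decay: float = 2e-5,
    maf_corr_bp: float = 10_000.0,
    n_founders: int = 100,
    mutation_rate: float = 0.002,
    chip_maf: float = 0.05,
    chip_prob: float = 0.5,
    seed: int | None = None,
) -> HaplotypePanel:
    """Generate a synthetic haplotype panel with distance-decaying LD.

    Parameters
    ----------
    n_hap, n_snp, region_bp
        Panel dimensions; positions are drawn uniformly over the region.
    maf_spec
        (a, b) of a Beta distribution; target minor allele frequencies are
        0.5 * Beta(a, b), skewed toward rare alleles.
    ld_decay
        LD decay rate per bp: the founder-switch probability across a gap of
        d bp is 1 - exp(-d * ld_decay).  0 gives the copying limit (adjacent
        r^2 near 1); large values give independent SNPs.
    maf_corr_bp
        Correlation length (bp) of the target-MAF process along the region.
    n_founders
        Size of the founder pool the mosaic copies from; smaller pools give
        stronger LD.
    mutation_rate
        Per-allele copy-error probability, keeps rare variation present.
    chip_maf, chip_prob
        SNPs with MAF >= chip_maf enter the chip independently with probability
        chip_prob (a thinning proxy for a commercial genotyping array).
    """
    if n_hap < 2 or n_hap % 2:
        raise ValueError("n_hap must be even and >= 2")
    if n_snp < 1 or region_bp < n_snp:
        raise ValueError("need n_snp >= 1 and region_bp >= n_snp")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(1, region_bp + 1), size=n_snp, replace=False)
    )
    gaps = np.diff(positions, prepend=positions[0])
    # target MAFs: Beta marginal spectrum with local (AR-1) correlation along
    # the region, so neighbouring SNPs tend to have similar frequencies — a
    # prerequisite for the high pairwise r^2 seen between nearby real SNPs.
    # The correlation length (maf_corr_bp) is much shorter than the region so
    # a single panel still spans the whole frequency spectrum.
    from scipy import stats as _st

    rho_f = np.exp(-gaps / maf_corr_bp)
    u = np.empty(n_snp)
    u[0] = rng.standard_normal()
    for j in range(1, n_snp):
        u[j] = rho_f[j] * u[j - 1] + math.sqrt(
            1.0 - rho_f[j] ** 2
        ) * rng.standard_normal()
    maf = 0.5 * _st.beta.ppf(_st.norm.cdf(u), maf_spec[0], maf_spec[1])
    maf = np.clip(maf, 1.0 / n_hap, 0.5)
    freq = np.where(rng.random(n_snp) < 0.5, maf, 1.0 - maf)

    # founder pool: per-founder latent Gaussian AR(1) along SNPs, thresholded
    # at the per-SNP target frequency (a Gaussian-copula Markov chain, so the
    # marginal frequency spectrum is preserved while nearby columns correlate)
    from scipy.special import ndtri

    rho = np.exp(-gaps * ld_decay / 2.0)
    z = np.empty((n_founders, n_snp))
    z[:, 0] = rng.standard_normal(n_founders)
    for j in range(1, n_snp):
        z[:, j] = rho[j] * z[:, j - 1] + math.sqrt(
            1.0 - rho[j] ** 2
        ) * rng.standard_normal(n_founders)
    founders = (z < ndtri(freq)[None, :]).astype(np.uint8)

    # mosaic copying from the founder pool with distance-dependent switching
    switch_p = 1.0 - np.exp(-gaps * ld_decay)
    hap = np.empty((n_hap, n_snp), dtype=np.uint8)
    template = rng.integers(0, n_founders, size=n_hap)
    for j in range(n_snp):
        if j > 0:
            sw = rng.random(n_hap) < switch_p[j]
            n_sw = int(sw.sum())
            if n_sw:
                template[sw] = rng.integers(0, n_founders, size=n_sw)
        col = founders[template, j]
        if mutation_rate > 0:
            flip = rng.random(n_hap) < mutation_rate
            col = col ^ flip
        hap[:, j] = col

    obs_maf = np.minimum(hap.mean(axis=0), 1.0 - hap.mean(axis=0))
    chip = (obs_maf >= chip_maf) & (rng.random(n_snp) < chip_prob)
    if not chip.any():
        chip[int(np.argmax(obs_maf))] = True
    return HaplotypePanel(hap, positions, chip)


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Empirical r^2 between two panel SNPs (squared haplotype correlation)."""
    x = panel.haplotypes[:, i].astype(float)
    y = panel.haplotypes[:, j].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


class _StudySampler:
    """Without-replacement haplotype sampling for one study.

    Haplotype indices are consumed as sampling proceeds (scan plus replication
    within a study share the pool); the panel itself is untouched, so it is
    implicitly restored between studies.
    """

    def __init__(self, panel: HaplotypePanel, causal_snp: int, risk_allele: int, rng):
        self.panel = panel
        self.rng = rng
        a = panel.haplotypes[:, causal_snp]
        if risk_allele == 0:
            a = 1 - a
        perm = rng.permutation(panel.n_hap)
        a_perm = a[perm]
        # each pool is in uniform random order; consuming from the front is a
        # uniform without-replacement draw within that allele class
        self._pools = [perm[a_perm == 0], perm[a_perm == 1]]
        self._ptr = [0, 0]
        self.f = float(a.mean())

    def _remaining(self, allele: int) -> int:
        return self._pools[allele].size - self._ptr[allele]

    def _take(self, allele: int, k: int) -> np.ndarray:
        if self._remaining(allele) < k:
            raise RuntimeError(
                f"panel exhausted: need {k} more haplotypes carrying allele "
                f"{allele} at the causal SNP"
            )
        p = self._ptr[allele]
        self._ptr[allele] = p + k
        return self._pools[allele][p : p + k]

    def sample(
        self, model: GeneralModel, n_case: int, n_ctrl: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Case and control haplotype index pairs, shapes (n_case, 2), (n_ctrl, 2)."""
        a1, a2 = model.genotype_relative_risks()
        f = self.f
        w = np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f) * a1, f**2 * a2])
        geno = self.rng.multinomial(n_case, w / w.sum())
        pairs = []
        for g, n_g in enumerate(geno):
            if n_g == 0:
                continue
            first = self._take(0 if g < 2 else 1, int(n_g))
            second = self._take(0 if g < 1 else 1, int(n_g))
            pairs.append(np.column_stack([first, second]))
        case = (
            np.concatenate(pairs, axis=0)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )
        # controls: a uniform without-replacement draw from the union of the
        # remaining pools — split the draw between pools hypergeometrically,
        # then shuffle before pairing
        total = 2 * n_ctrl
        n0, n1 = self._remaining(0), self._remaining(1)
        if n0 + n1 < total:
            raise RuntimeError("panel exhausted: not enough haplotypes for controls")
        if n0 == 0 or n1 == 0:
            k1 = total if n0 == 0 else 0
        else:
            k1 = int(self.rng.hypergeometric(n1, n0, total))
        chosen = np.concatenate([self._take(1, k1), self._take(0, total - k1)])
        ctrl = self.rng.permutation(chosen).reshape(n_ctrl, 2)
        return case, ctrl


def sample_cases_controls(
    panel: HaplotypePanel,
    causal_snp: int,
    model: GeneralModel,
    n_case: int,
    n_ctrl: int,
    seed: int | None = None,
    risk_allele: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample case and control genotype matrices (individuals x SNPs).

    Cases are ascertained through the causal genotype distribution implied by
    the disease model (weights proportional to HWE frequencies times genotype
    relative risks, with f the panel frequency of the risk allele); controls
    are an unphenotyped population sample.  All haplotype draws are without
    replacement within the call.
    """
    rng = np.random.default_rng(seed)
    sampler = _StudySampler(panel, causal_snp, risk_allele, rng)
    case_idx, ctrl_idx = sampler.sample(model, n_case, n_ctrl)
    H = panel.haplotypes
    case_g = H[case_idx[:, 0]] + H[case_idx[:, 1]]
    ctrl_g = H[ctrl_idx[:, 0]] + H[ctrl_idx[:, 1]]
    return case_g, ctrl_g


@dataclass(frozen=True)
class StudyOutcome:
    """Result of one simulated scan -> replication -> deviation study."""

    outcome: str
    causal_snp: int
    risk_allele: int
    hit_snp: int
    r2_hit: float
    scan_p: float
    replication_p: float | None = None
    deviation_p: float | None = None
    beta_hat: float | None = None
    gamma_hat: float | None = None


def _genotype_counts(geno: np.ndarray) -> np.ndarray:
    """Per-SNP genotype counts, shape (n_snp, 3), from an (n, n_snp) matrix."""
    return np.stack([(geno == g).sum(axis=0) for g in range(3)], axis=-1)


def _general_estimates(case_c: np.ndarray, ctrl_c: np.ndarray):
    """Saturated-fit (beta_hat, gamma_hat) from 3-cell counts; None on zero cells."""
    if np.any(case_c == 0) or np.any(ctrl_c == 0):
        return None, None
    l = np.log(case_c) - np.log(ctrl_c)
    beta = 0.5 * (l[2] - l[0])
    gamma = l[1] - 0.5 * (l[0] + l[2])
    return float(beta), float(gamma)


def run_study(
    panel: HaplotypePanel,
    causal_snp: int,
    model: GeneralModel,
    n_case: int = 2000,
    n_ctrl: int = 2000,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    seed: int | None = None,
    risk_allele: int = 1,
) -> StudyOutcome:
    """Simulate one complete association + replication study.

    Trend tests run on chip SNPs only; the hit SNP is the chip SNP with the
    smallest scan p-value (ties broken by lowest SNP index).  The cascade is:
    scan p < thresholds[0], replication trend p < thresholds[1] on a fresh
    sample genotyped at the hit SNP only, then a deviation test on the
    replication counts at level thresholds[2].  A replication table on which
    the deviation test cannot be fitted (an empty phenotype-by-genotype cell)
    counts as non-significant.
    """
    scan_t, rep_t, dev_t = thresholds
    rng = np.random.default_rng(seed)
    sampler = _StudySampler(panel, causal_snp, risk_allele, rng)

    case_idx, ctrl_idx = sampler.sample(model, n_case, n_ctrl)
    H = panel.haplotypes
    chip = np.flatnonzero(panel.chip_mask)
    case_g = H[case_idx[:, 0]][:, chip] + H[case_idx[:, 1]][:, chip]
    ctrl_g = H[ctrl_idx[:, 0]][:, chip] + H[ctrl_idx[:, 1]][:, chip]
    stat, pvals = trend_stats(_genotype_counts(case_g), _genotype_counts(ctrl_g))
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    hit_local = int(np.argmin(pvals))  # argmin takes the lowest index on ties
    hit = int(chip[hit_local])
    scan_p = float(pvals[hit_local])
    r2 = pairwise_r2(panel, causal_snp, hit)

    base = dict(
        causal_snp=causal_snp,
        risk_allele=risk_allele,
        hit_snp=hit,
        r2_hit=r2,
        scan_p=scan_p,
    )
    if scan_p >= scan_t:
        return StudyOutcome(outcome="undetected", **base)

    # replication: fresh individuals, genotyped at the hit SNP only
    rep_case_idx, rep_ctrl_idx = sampler.sample(model, n_case, n_ctrl)
    rc = H[rep_case_idx[:, 0], hit] + H[rep_case_idx[:, 1], hit]
    rs = H[rep_ctrl_idx[:, 0], hit] + H[rep_ctrl_idx[:, 1], hit]
    case_c = np.bincount(rc, minlength=3)[:3]
    ctrl_c = np.bincount(rs, minlength=3)[:3]
    _, rep_p = trend_stats(case_c.astype(float), ctrl_c.astype(float))
    rep_p = float(rep_p) if np.isfinite(rep_p) else 1.0
    beta_hat, gamma_hat = _general_estimates(case_c, ctrl_c)
    if rep_p >= rep_t:
        return StudyOutcome(outcome="undetected", replication_p=rep_p, **base)

    dev_stat, dev_p, _, _ = deviation_stats(
        case_c.astype(float), ctrl_c.astype(float)
    )
    dev_p = float(dev_p) if np.isfinite(dev_p) else 1.0  # unfittable => non-sig
    outcome = "assoc_plus_deviation" if dev_p < dev_t else "assoc_only"
    return StudyOutcome(
        outcome=outcome,
        replication_p=rep_p,
        deviation_p=dev_p,
        beta_hat=beta_hat,
        gamma_hat=gamma_hat,
        **base,
    )


def run_experiment(
    panel: HaplotypePanel,
    model: GeneralModel,
    snp_set=None,
    alleles: tuple[int, ...] = (0, 1),
    n_case: int = 2000,
    n_ctrl: int = 2000,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run one study per (causal SNP, risk allele) and tabulate the outcomes.

    By default every polymorphic panel SNP is presumed causal in turn, once per
    allele orientation (dominant and recessive models are not allele-symmetric,
    so the two orientations are genuinely different studies).  Studies are
    seeded independently from `seed`, so the outcome table is reproducible
    byte-for-byte.
    """
    if snp_set is None:
        freq = panel.frequencies
        snp_set = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    snp_set = np.asarray(snp_set, dtype=int)
    if snp_set.size == 0:
        raise ValueError("snp_set must be nonempty")
    jobs = [(int(s), a) for s in snp_set for a in alleles]
    child_seeds = np.random.SeedSequence(seed).generate_state(len(jobs)) % (2**31)
    rows = []
    for (snp, allele), s in zip(jobs, child_seeds):
        out = run_study(
            panel,
            snp,
            model,
            n_case=n_case,
            n_ctrl=n_ctrl,
            thresholds=thresholds,
            seed=int(s),
            risk_allele=allele,
        )
        rows.append(out.__dict__)
    return pd.DataFrame(rows)


def aggregate_outcomes(outcomes: pd.DataFrame) -> pd.Series:
    """One aggregate row: outcome percentages and the deviation rate among hits."""
    n = len(outcomes)
    counts = outcomes["outcome"].value_counts()
    pct = {k: 100.0 * counts.get(k, 0) / n for k in OUTCOMES}
    n_assoc = counts.get("assoc_only", 0) + counts.get("assoc_plus_deviation", 0)
    dev_rate = (
        100.0 * counts.get("assoc_plus_deviation", 0) / n_assoc if n_assoc else math.nan
    )
    return pd.Series(
        {
            "n_studies": n,
            "pct_undetected": pct["undetected"],
            "pct_assoc_only": pct["assoc_only"],
            "pct_assoc_plus_deviation": pct["assoc_plus_deviation"],
            "deviation_rate_among_assoc": dev_rate,
            "n_assoc": int(n_assoc),
        }
    )


def outcome_by_ld_bins(outcomes: pd.DataFrame, width: float = 0.1) -> pd.DataFrame:
    """Outcome counts and proportions per r^2 bin between causal and hit SNPs.

    Bins are labelled by their upper edge.  Proportions are NaN in empty bins;
    the detected-only deviation rate is NaN where nothing was detected.
    """
    edges = np.arange(0.0, 1.0 + width / 2, width)
    edges[-1] = 1.0 + 1e-9
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = outcomes[(outcomes.r2_hit >= lo) & (outcomes.r2_hit < hi)]
        n = len(sel)
        c = sel["outcome"].value_counts() if n else {}
        cnt = {k: int(c.get(k, 0)) for k in OUTCOMES}
        n_det = cnt["assoc_only"] + cnt["assoc_plus_deviation"]
        rows.append(
            {
                "r2_bin_upper": round(min(hi, 1.0), 10),
                "n": n,
                **{f"n_{k}": cnt[k] for k in OUTCOMES},
                **{
                    f"prop_{k}": (cnt[k] / n if n else math.nan) for k in OUTCOMES
                },
                "deviation_rate_among_detected": (
                    cnt["assoc_plus_deviation"] / n_det if n_det else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# -- panel I/O (IMPUTE-style text formats) -----------------------------------


def write_panel(panel: HaplotypePanel, prefix: str) -> None:
    """Write `prefix`.haps / .legend / .chip (plain text, round-trips exactly).

    .haps: one SNP per row, space-separated 0/1 alleles (one column per
    haplotype); .legend: header `id position allele0 allele1`; .chip: one 0/1
    line per SNP marking chip membership.
    """
    np.savetxt(prefix + ".haps", panel.haplotypes.T, fmt="%d", delimiter=" ")
    with open(prefix + ".legend", "w") as fh:
        fh.write("id position allele0 allele1\n")
        for sid, pos in zip(panel.snp_ids, panel.positions):
            fh.write(f"{sid} {pos} 0 1\n")
    np.savetxt(prefix + ".chip", panel.chip_mask.astype(int), fmt="%d")


def read_panel(prefix: str) -> HaplotypePanel:
    """Read a panel written by :func:`write_panel`."""
    hap = np.loadtxt(prefix + ".haps", dtype=np.uint8, ndmin=2).T
    ids, positions = [], []
    with open(prefix + ".legend") as fh:
        header = fh.readline().split()
        if header[:2] != ["id", "position"]:
            raise ValueError("legend file must start with 'id position ...' header")
        for line in fh:
            parts = line.split()
            ids.append(parts[0])
            positions.append(int(parts[1]))
    chip = np.loadtxt(prefix + ".chip", dtype=np.int64, ndmin=1).astype(bool)
    return HaplotypePanel(hap, np.array(positions), chip, snp_ids=ids)
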