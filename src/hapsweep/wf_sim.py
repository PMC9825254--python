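"""Sexed diploid Wright-Fisher engines with explicit X-chromosome transmission.

Two engines share one parameterization (:class:`SimParams`):

* :class:`Population` — a full individual-based engine carrying an
  infinite-sites neutral 10-kb locus with recombination, used for neutral
  calibration, single-origin standing-variation runs and haplotype sampling.
* :class:`SelectedLocusSim` — a sparse engine (numba kernel) that tracks only
  carriers of the focal allele with per-copy origin labels.  Neutral sites are
  selectively inert, so its selected-locus law is exactly the full engine's;
  it is orders of magnitude faster and drives the replicated experiments.

Dosage compensation is assumed throughout: a hemizygous X male carrying the
allele has the fitness of a homozygous female (1+s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .io_formats import AUTOSOME, X, HaplotypeMatrix


def x_autosome_theta_ratio(n_females: int = 1, n_males: int = 1) -> float:
    """theta_X / theta_autosome from chromosome-copy counting.

    Females carry two X copies, males one; every individual carries two
    autosomal copies.  With an equal sex ratio this is 3/4.
    """
    x_copies = 2 * n_females + n_males
    autosome_copies = 2 * (n_females + n_males)
    return x_copies / autosome_copies


@dataclass
class SimParams:
    """Full parameterization of one forward simulation.

    ``theta_adaptive`` and ``theta_neutral`` are population-scaled rates
    4*Ne*mu in the autosomal convention (Ne = diploid count); per-copy rates
    are derived as theta/(4*Ne).  An X-class simulation of the same ``ne``
    individuals automatically has 3/4 the mutational input, matching
    theta_X = 0.75 * theta_autosome under an equal sex ratio.
    """

    ne: int = 1000
    chrom_class: str = AUTOSOME
    theta_adaptive: float = 0.0
    theta_neutral: float = 40.0  # per 10-kb locus (0.004 per bp)
    s: float = 0.0
    h: float = 0.5
    rho_cm_per_bp: float = 5e-7
    locus_bp: int = 10_000
    q: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ne < 10:
            raise ValueError("ne must be >= 10")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        if self.theta_adaptive < 0 or self.theta_neutral < 0:
            raise ValueError("theta values must be >= 0")
        if self.chrom_class not in (AUTOSOME, X):
            raise ValueError(f"unknown chrom_class {self.chrom_class!r}")

    @property
    def mu_adaptive(self) -> float:
        """Adaptive mutation probability per transmitted copy per generation."""
        return self.theta_adaptive / (4 * self.ne)

    @property
    def mu_neutral_locus(self) -> float:
        """Neutral mutation probability per copy per generation, whole locus."""
        return self.theta_neutral / (4 * self.ne)

    @property
    def morgans_locus(self) -> float:
        """Crossover probability per gamete over the locus (cM/bp / 100 * L)."""
        return self.rho_cm_per_bp / 100.0 * self.locus_bp


def rescale(params: SimParams) -> SimParams:
    """Rescale by Q: Ne -> Ne/Q, s -> s*Q, mutation and recombination *Q.

    theta = 4*Ne*mu and Ne*s are invariant (theta fields are stored scaled
    already, so only Ne, s and rho change).  Generation counts downstream
    shrink by Q.  Rescaling is accurate for weak selection; a rescaled
    s >= 0.1 triggers a validity warning.
    """
    if params.q < 1:
        raise ValueError("Q must be >= 1")
    if params.q == 1:
        return params
    ne2 = int(round(params.ne / params.q))
    if ne2 < 10:
        raise ValueError("rescaled Ne must be >= 10")
    s2 = params.s * params.q
    if abs(s2) >= 0.1:
        warnings.warn(
            f"rescaled |s| = {abs(s2):.3g} >= 0.1; rescaling validity is "
            "questionable for strong selection",
            stacklevel=2,
        )
    return replace(
        params,
        ne=ne2,
        s=s2,
        rho_cm_per_bp=params.rho_cm_per_bp * params.q,
        q=1.0,
    )


# ---------------------------------------------------------------------------
# Sparse selected-locus engine
# ---------------------------------------------------------------------------

class SelectedLocusSim:
    """Selected-locus origin dynamics via the sparse kernel.

    Supports sex-specific selection coefficients (sexual antagonism) and
    phase switches (dominance shifts, cessation of recurrent mutation).
    """

    def __init__(self, params: SimParams, seed: int):
        self.params = params
        self.n = params.ne
        self.is_x = params.chrom_class == X
        n = self.n
        self.sex = np.zeros(n + 8, dtype=np.int8)
        self.a = np.zeros(n + 8, dtype=np.int64)
        self.b = np.zeros(n + 8, dtype=np.int64)
        self.n_carr = 0
        self.n_f = n // 2
        self.gen = 0
        self.next_origin = 1
        cap = max(100_000, int(params.theta_adaptive * 200_000) + 1000)
        self.origin_gen = np.zeros(cap, dtype=np.int64)
        self._scratch = (
            np.zeros(_kernel.MAX_ORG, dtype=np.int64),  # org_ids
            np.zeros(_kernel.MAX_ORG, dtype=np.float64),  # gpf
            np.zeros(_kernel.MAX_ORG, dtype=np.float64),  # gpm
            np.zeros(_kernel.MAX_ORG, dtype=np.int64),  # cnt_md
            np.zeros(_kernel.MAX_ORG, dtype=np.int64),  # cnt_ms
            np.zeros(_kernel.MAX_ORG, dtype=np.int64),  # cnt_pd
            np.zeros(_kernel.MAX_ORG, dtype=np.int64),  # cnt_ps
            np.zeros(n + 8, dtype=np.int64),  # buf_mat
            np.zeros(n + 8, dtype=np.int64),  # buf_pat
            np.zeros(n + 8, dtype=np.int8),  # sex2
            np.zeros(n + 8, dtype=np.int64),  # a2
            np.zeros(n + 8, dtype=np.int64),  # b2
        )
        _kernel.seed_kernel(int(seed) % (2**31 - 1))
        self._py_rng = np.random.default_rng(seed)

    # -- state helpers ---------------------------------------------------
    def total_copies(self) -> int:
        if self.is_x:
            return 2 * self.n_f + (self.n - self.n_f)
        return 2 * self.n

    def mutant_copies(self) -> int:
        aa = self.a[: self.n_carr]
        bb = self.b[: self.n_carr]
        return int((aa > 0).sum() + (bb > 0).sum())

    def frequency(self) -> float:
        return self.mutant_copies() / self.total_copies()

    def introduce_single_copy(self, origin: int | None = None) -> None:
        """Place one focal copy in a random individual (copy-weighted)."""
        if origin is None:
            origin = self.next_origin
            self.origin_gen[origin] = self.gen
            self.next_origin += 1
        n_m = self.n - self.n_f
        if self.is_x:
            p_female = 2 * self.n_f / (2 * self.n_f + n_m)
        else:
            p_female = self.n_f / self.n
        i = self.n_carr
        if self._py_rng.random() < p_female:
            self.sex[i] = 1
            self.a[i], self.b[i] = origin, 0
        else:
            self.sex[i] = 0
            self.a[i], self.b[i] = origin, (-1 if self.is_x else 0)
        self.n_carr += 1

    # -- dynamics --------------------------------------------------------
    def run_phase(
        self,
        max_gens: int,
        s: float | None = None,
        h: float | None = None,
        mu: float | None = None,
        s_female: float | None = None,
        s_male: float | None = None,
        stop_on_fix: bool = False,
        stop_on_loss: bool = False,
        stop_freq: float = 0.0,
    ) -> int:
        """Run until fixation/loss/frequency threshold or ``max_gens`` more
        generations; returns a ``_kernel.STATUS_*`` code."""
        p = self.params
        s = p.s if s is None else s
        h = p.h if h is None else h
        mu = p.mu_adaptive if mu is None else mu
        s_f = s if s_female is None else s_female
        s_m = s if s_male is None else s_male
        status, gen, n_carr, n_f, nxt = _kernel.run_phase(
            self.sex, self.a, self.b, self.n_carr, self.n_f, self.n,
            self.is_x, s_f, h, s_m, h, mu,
            self.gen, self.gen + max_gens,
            stop_on_fix, stop_on_loss, stop_freq,
            self.origin_gen, self.next_origin,
            *self._scratch,
        )
        if status == _kernel.STATUS_OVERFLOW:
            raise RuntimeError("too many simultaneously segregating origins")
        if status == _kernel.STATUS_SEX_EXTINCT:
            raise RuntimeError("one sex went extinct (pathological N)")
        self.gen, self.n_carr, self.n_f, self.next_origin = gen, n_carr, n_f, nxt
        return status

    # -- sampling --------------------------------------------------------
    def copy_labels(self) -> np.ndarray:
        """Origin label per chromosome copy in the census (0 = wild type)."""
        labels = []
        for i in range(self.n_carr):
            labels.append(self.a[i])
            if not (self.is_x and self.sex[i] == 0):
                labels.append(self.b[i])
        n_wt = self.total_copies() - len(labels)
        return np.concatenate([np.asarray(labels, dtype=np.int64), np.zeros(n_wt, dtype=np.int64)])

    def sample_origins(self, k: int = 100) -> np.ndarray:
        """Origin labels of ``k`` copies sampled uniformly without replacement."""
        labels = self.copy_labels()
        if k > labels.size:
            raise ValueError("sample size exceeds chromosome copy count")
        return self._py_rng.choice(labels, size=k, replace=False)


# ---------------------------------------------------------------------------
# Full individual-based engine with a neutral infinite-sites locus
# ---------------------------------------------------------------------------

class Population:
    """Individual-based WF population carrying a recombining neutral locus.

    Neutral mutations arise as infinite sites at rate theta_neutral/(4*Ne)
    per copy per generation at uniform positions; the selected site sits at
    the locus center.  X males use only their first chromosome row.
    """

    def __init__(self, params: SimParams, rng: np.random.Generator | None = None):
        self.params = params
        self.rng = rng or np.random.default_rng(params.seed)
        n = params.ne
        self.is_x = params.chrom_class == X
        self.sex = self.rng.random(n) < 0.5
        if self.sex.sum() in (0, n):  # tiny-N guard
            self.sex[: n // 2] = True
            self.sex[n // 2:] = False
        self.sel = np.zeros((n, 2), dtype=np.int64)
        if self.is_x:
            self.sel[~self.sex, 1] = -1
        self.G = np.zeros((2 * n, 0), dtype=np.int8)
        self.positions = np.zeros(0, dtype=np.float64)
        self.gen = 0
        self.next_origin = 1
        self.origin_gen: dict[int, int] = {}

    # -- bookkeeping -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.sel.shape[0]

    def valid_copy_rows(self) -> np.ndarray:
        """Row indices of chromosome copies that exist (X males: first only)."""
        n = self.n
        rows = []
        for i in range(n):
            rows.append(2 * i)
            if not (self.is_x and not self.sex[i]):
                rows.append(2 * i + 1)
        return np.asarray(rows)

    def mutant_copies(self) -> int:
        cnt = int((self.sel[:, 0] > 0).sum())
        second = self.sel[:, 1]
        cnt += int((second > 0).sum())
        return cnt

    def total_copies(self) -> int:
        if self.is_x:
            return int(2 * self.sex.sum() + (~self.sex).sum())
        return 2 * self.n

    def frequency(self) -> float:
        return self.mutant_copies() / self.total_copies()

    def introduce_single_copy(self) -> int:
        """Add one focal mutation on a random existing copy; returns origin id."""
        rows = self.valid_copy_rows()
        r = int(self.rng.choice(rows))
        i, slot = divmod(r, 2)
        origin = self.next_origin
        self.sel[i, slot] = origin
        self.origin_gen[origin] = self.gen
        self.next_origin += 1
        return origin

    # -- fitness ----------------------------------------------------------
    def _fitness(self, s: float, h: float) -> np.ndarray:
        cnt = (self.sel > 0).sum(axis=1)
        w = np.ones(self.n)
        if self.is_x:
            males = ~self.sex
            hemi = males & (self.sel[:, 0] > 0)
            fem = self.sex
            w[fem & (cnt == 1)] = 1 + h * s
            w[fem & (cnt == 2)] = 1 + s
            w[hemi] = 1 + s  # dosage compensation
        else:
            w[cnt == 1] = 1 + h * s
            w[cnt == 2] = 1 + s
        return np.maximum(w, 0.0)

    # -- one generation ----------------------------------------------------
    def step(self, s: float | None = None, h: float | None = None,
             mu_adaptive: float | None = None) -> None:
        p = self.params
        s = p.s if s is None else s
        h = p.h if h is None else h
        mu_a = p.mu_adaptive if mu_adaptive is None else mu_adaptive
        rng = self.rng
        n = self.n
        w = self._fitness(s, h)
        f_idx = np.flatnonzero(self.sex)
        m_idx = np.flatnonzero(~self.sex)
        if f_idx.size == 0 or m_idx.size == 0:
            raise RuntimeError("one sex went extinct (pathological N)")
        wf = w[f_idx] / w[f_idx].sum()
        wm = w[m_idx] / w[m_idx].sum()
        mothers = rng.choice(f_idx, size=n, p=wf)
        fathers = rng.choice(m_idx, size=n, p=wm)
        sex2 = rng.random(n) < 0.5
        if sex2.sum() in (0, n):
            sex2[0] = not sex2[0]

        m = self.G.shape[1]
        G2 = np.zeros((2 * n, m), dtype=np.int8)
        sel2 = np.zeros((n, 2), dtype=np.int64)

        # maternal gametes (always recombining)
        self._make_gametes(mothers, G2, sel2, slot=0, recombine=True)
        # paternal gametes
        if self.is_x:
            daughters = np.flatnonzero(sex2)
            # father's single X passed unrecombined to daughters
            rows = 2 * fathers[daughters]
            G2[2 * daughters + 1] = self.G[rows]
            sel2[daughters, 1] = self.sel[fathers[daughters], 0]
            sons = np.flatnonzero(~sex2)
            sel2[sons, 1] = -1
        else:
            self._make_gametes(fathers, G2, sel2, slot=1, recombine=True)

        self.sex = sex2
        self.sel = sel2
        self.G = G2
        self._mutate(mu_a)
        self.gen += 1
        if self.gen % 50 == 0:
            self._prune()

    def _make_gametes(self, parents: np.ndarray, G2: np.ndarray, sel2: np.ndarray,
                      slot: int, recombine: bool) -> None:
        rng = self.rng
        n = parents.size
        p = self.params
        cx = rng.poisson(p.morgans_locus, size=n) if recombine else np.zeros(n, dtype=int)
        start = rng.integers(0, 2, size=n)
        plain = cx == 0
        rows = 2 * parents + start
        G2[(2 * np.arange(n) + slot)[plain]] = self.G[rows[plain]]
        sel2[plain, slot] = self.sel[parents[plain], start[plain]]
        mid = p.locus_bp / 2.0
        for i in np.flatnonzero(~plain):
            bp = np.sort(rng.uniform(0, p.locus_bp, size=cx[i]))
            # parity of crossovers left of each site decides the source copy
            parity = np.searchsorted(bp, self.positions) % 2
            src = (start[i] + parity) % 2
            pa = self.G[2 * parents[i]]
            pb = self.G[2 * parents[i] + 1]
            G2[2 * i + slot] = np.where(src == 0, pa, pb)
            sel_src = (start[i] + (np.searchsorted(bp, mid) % 2)) % 2
            sel2[i, slot] = self.sel[parents[i], sel_src]

    def _mutate(self, mu_adaptive: float) -> None:
        rng = self.rng
        p = self.params
        rows = self.valid_copy_rows()
        # neutral infinite-sites mutations
        n_new = rng.poisson(p.mu_neutral_locus * rows.size)
        if n_new:
            existing = set(self.positions.tolist())
            new_pos = []
            while len(new_pos) < n_new:
                x = float(rng.uniform(0, p.locus_bp))
                if x not in existing:
                    existing.add(x)
                    new_pos.append(x)
            cols = np.zeros((self.G.shape[0], n_new), dtype=np.int8)
            hit = rng.choice(rows, size=n_new)
            cols[hit, np.arange(n_new)] = 1
            self.G = np.concatenate([self.G, cols], axis=1)
            self.positions = np.concatenate([self.positions, new_pos])
        # adaptive mutations on wild-type copies
        if mu_adaptive > 0:
            hits = rows[rng.random(rows.size) < mu_adaptive]
            for r in hits:
                i, slot = divmod(int(r), 2)
                if self.sel[i, slot] == 0:
                    self.sel[i, slot] = self.next_origin
                    self.origin_gen[self.next_origin] = self.gen
                    self.next_origin += 1

    def _prune(self) -> None:
        """Drop neutral columns fixed or lost among existing copies."""
        if self.G.shape[1] == 0:
            return
        rows = self.valid_copy_rows()
        col = self.G[rows]
        seg = (col.sum(axis=0) > 0) & (col.sum(axis=0) < rows.size)
        self.G = self.G[:, seg]
        self.positions = self.positions[seg]

    # -- sampling ----------------------------------------------------------
    def sample_haplotypes(
        self, k: int = 100, rng: np.random.Generator | None = None
    ) -> tuple[HaplotypeMatrix, np.ndarray]:
        """Sample ``k`` chromosome copies uniformly without replacement.

        Returns the haplotype matrix over segregating neutral sites plus the
        selected site (locus center), and the per-copy origin labels.
        """
        rng = rng or self.rng
        rows = self.valid_copy_rows()
        if k > rows.size:
            raise ValueError("sample size exceeds chromosome copy count")
        pick = rng.choice(rows, size=k, replace=False)
        sel_alleles = np.array(
            [self.sel[r // 2, r % 2] for r in pick], dtype=np.int64
        )
        sub = self.G[pick]
        seg = (sub.sum(axis=0) > 0) & (sub.sum(axis=0) < k)
        sub = sub[:, seg]
        pos = self.positions[seg]
        mid = self.params.locus_bp / 2.0
        all_pos = np.concatenate([pos, [mid]])
        all_cols = np.concatenate([sub, (sel_alleles > 0).astype(np.int8)[:, None]], axis=1)
        order = np.argsort(all_pos, kind="stable")
        all_pos = all_pos[order]
        all_cols = all_cols[:, order]
        ipos = np.floor(all_pos).astype(np.int64) + 1
        for j in range(1, ipos.size):  # enforce strictly increasing
            if ipos[j] <= ipos[j - 1]:
                ipos[j] = ipos[j - 1] + 1
        mat = HaplotypeMatrix(
            all_cols, ipos, chrom_label="sim", chrom_class=self.params.chrom_class
        )
        return mat, sel_alleles


def step_generation(pop: Population, s: float | None = None, h: float | None = None) -> Population:
    """Functional wrapper over :meth:`Population.step` (updates in place)."""
    pop.step(s=s, h=h)
    return pop


def burn_in(pop: Population, generations: int | None = None) -> Population:
    """Neutral burn-in (s = 0); default length 10*Ne generations."""
    gens = generations if generations is not None else 10 * pop.params.ne
    for _ in range(gens):
        pop.step(s=0.0, h=0.5, mu_adaptive=0.0)
    return pop
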