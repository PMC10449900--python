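"""Whole-genome amplification gain and chimera formation.

Two regimes are modelled:

* ``mda`` — conventional tube MDA: per-fragment copy number is lognormal
  with a large log-sigma, unclipped, producing the heavy-tailed gain that
  drives extreme coverage peaks.
* ``dmda`` — droplet MDA: per-fragment gain is lognormal with a small
  log-sigma and the total copies per droplet are capped (reagent-limited
  amplification inside a picoliter volume).

Chimeras form on individual amplified copies: fold-back inversions (the
molecule rejoins the reverse complement of its own prefix), tandem
duplications of an internal window, and intermolecular joins restricted to
fragments sharing a droplet.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from dropwgs.config import SimConfig
from dropwgs.models import Amplicon, ChimeraEvent, Fragment

logger = logging.getLogger(__name__)


def _copy_numbers(rng, n: int, mean: float, sigma: float) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    return np.round(rng.lognormal(mu, sigma, size=n)).astype(np.int64)


def _cap_group(copies: list[int], cap: int) -> list[int]:
    """Reduce copy numbers so the group total never exceeds ``cap``."""
    total = sum(copies)
    while total > cap:
        i = max(range(len(copies)), key=lambda j: copies[j])
        if copies[i] == 0:  # pragma: no cover - cap < number of fragments
            break
        copies[i] -= 1
        total -= 1
    return copies


def amplify(
    fragments: list[Fragment],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Amplicon]:
    """Draw amplification gain and chimera events for every fragment."""
    gm = config.gain_model
    cr = config.chimera_rates
    n = len(fragments)
    if n == 0:
        return []

    if gm.mode == "mda":
        copies = _copy_numbers(rng, n, gm.mean_copies, gm.mda_log_sigma)
        amplicons = [Amplicon(f, int(c)) for f, c in zip(fragments, copies)]
        groups = {None: amplicons}
    else:
        copies = np.maximum(
            _copy_numbers(rng, n, gm.mean_copies, gm.dmda_log_sigma), 1
        )
        amplicons = [Amplicon(f, int(c)) for f, c in zip(fragments, copies)]
        groups = defaultdict(list)
        for a in amplicons:
            groups[a.fragment.droplet_id].append(a)
        for group in groups.values():
            capped = _cap_group([a.copy_number for a in group], gm.dmda_cap_copies)
            for a, c in zip(group, capped):
                a.copy_number = c

    # intramolecular chimeras, drawn per amplified copy
    p_inv, p_dup = cr.inversion_per_amplicon, cr.duplication_per_amplicon
    if p_inv > 0 or p_dup > 0:
        for a in amplicons:
            if a.copy_number == 0:
                continue
            u = rng.random(a.copy_number)
            flen = a.fragment.length
            for ci in np.flatnonzero(u < p_inv + p_dup).tolist():
                if u[ci] < p_inv:
                    low = max(1, flen // 10, cr.inv_min_arm)
                    if low >= flen:
                        continue
                    b = int(rng.integers(low, flen))
                    a.chimera_events.append(ChimeraEvent("INVERSION", ci, breakpoint=b))
                elif flen > cr.dup_min_len + 1:
                    w = int(rng.integers(cr.dup_min_len, min(cr.dup_max_len, flen - 1)))
                    x = int(rng.integers(0, flen - w))
                    a.chimera_events.append(
                        ChimeraEvent("DUPLICATION", ci, dup_start=x, dup_end=x + w)
                    )

    # intermolecular joins: only between fragments sharing a droplet (the
    # whole tube counts as one group in bulk-MDA mode)
    if cr.intermolecular_per_droplet > 0:
        for droplet, group in groups.items():
            if rng.random() >= cr.intermolecular_per_droplet:
                continue
            usable = [a for a in group if a.copy_number > 0]
            if len(usable) < 2:
                logger.debug(
                    "intermolecular chimera skipped in droplet %s: "
                    "single fragment (physically impossible)", droplet,
                )
                continue
            i, j = rng.choice(len(usable), size=2, replace=False).tolist()
            host, partner = usable[i], usable[j]
            ci = int(rng.integers(0, host.copy_number))
            host.chimera_events = [e for e in host.chimera_events if e.copy_index != ci]
            host.chimera_events.append(
                ChimeraEvent(
                    "INTERMOLECULAR", ci,
                    breakpoint=int(rng.integers(1, host.fragment.length)),
                    partner=partner.fragment,
                    partner_breakpoint=int(rng.integers(0, partner.fragment.length - 1)),
                )
            )
    return amplicons
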