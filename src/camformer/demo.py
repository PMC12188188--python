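"""The desk-scale demonstration library: fixed study conditions used by the
worked example, the test suite and the acceptance script.

The library plants four motifs with a small cis-regulatory grammar:

* ``ACT`` (TGACTCAT, +2.0): a strong activator.
* ``REP`` (CCGGAAGT, -2.0): a strong repressor.
* ``IME`` (GCCGCC, +0.8): a weak activator whose consensus is *contained*
  within the ``UME`` site, so scanner hits of IME inside UME sites overlap —
  the synthetic analogue of a repressor motif enclosing an activator core.
* ``UME`` (TAGCCGCCGA, -2.2): a repressor; co-occurrence with IME carries an
  additional -1.2 interaction, so IME's apparent effect flips sign in UME
  context.

Effects are in latent expression units; the GC coefficient (+1.0 per unit GC
fraction of the insert) adds the mild compositional trend seen in reporter
data.  The readout uses 18 bins and 100 cells per promoter with unit
cell-level noise — the precise-readout (test-like) regime.
"""

from __future__ import annotations

from .simulate import InteractionSpec, LibrarySpec, motif_from_consensus

DEMO_MOTIFS = {
    "ACT": ("TGACTCAT", 2.0, 0.5),
    "REP": ("CCGGAAGT", -2.0, 0.5),
    "IME": ("GCCGCC", 0.8, 0.35),
    "UME": ("TAGCCGCCGA", -2.2, 0.35),
}
DEMO_INTERACTION = ("IME", "UME", -1.2)


def demo_library_spec(n: int = 20_000, seed: int = 0,
                      cells_per_promoter: int = 100) -> LibrarySpec:
    motifs = [motif_from_consensus(name, cons, eff, prob)
              for name, (cons, eff, prob) in DEMO_MOTIFS.items()]
    return LibrarySpec(
        n=n, seed=seed, baseline=0.0, gc_coeff=1.0,
        motifs=motifs,
        interactions=[InteractionSpec(*DEMO_INTERACTION)],
        n_bins=18, cells_per_promoter=cells_per_promoter, cell_noise_sd=1.0)
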