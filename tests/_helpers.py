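"""Shared oracle constructions for the test suite."""

from acatpk.params import GICompartment, GIPhysiology


def cat_chain(n_si: int, total_transit: float, ka: float, peff: float) -> GIPhysiology:
    """Transit-only oracle physiology: negligible gastric residence, ``n_si``
    equal small-intestine compartments with absorption constant ``ka`` (1/h)
    and a non-absorbing colon sink. In this limit the fraction absorbed has
    the closed form Fa = 1 − (1 + ka·T/n)^(−n)."""
    asf = ka / (2.0 * peff * 3600.0)  # compartment radius fixed at 1 cm
    comps = [GICompartment("stomach", 47.0, 9.67, 1e-3, 1.3, 0.0)]
    for i in range(n_si):
        comps.append(
            GICompartment(f"si{i + 1}", 100.0, 1.0, total_transit / n_si, 6.5, asf)
        )
    comps.append(GICompartment("colon", 50.0, 2.4, 13.5, 6.8, 0.0))
    return GIPhysiology(tuple(comps), tuple(f"si{i + 1}" for i in range(n_si)))
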