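"""Build the skirt, commissural attachments, and a leaflet for both valves.

Each soft-good surface is a Gordon (or loft) surface over a curve network;
the number printed for each is the worst distance between the surface and
any of its defining curves, which should sit at numerical zero: the surface
passes through its network exactly.
"""

import numpy as np

from thvforge import config, softgoods


def network_error(surface, net, n=50):
    ts = np.linspace(0, 1, n)
    errs = []
    for j, uc in enumerate(net.u_curves):
        iso = surface.evaluate_grid(ts, [net.v_stations[j]])[:, 0, :]
        errs.append(np.abs(iso - uc.evaluate(ts)).max())
    for i, vc in enumerate(net.v_curves):
        iso = surface.evaluate_grid([net.u_stations[i]], ts)[0]
        errs.append(np.abs(iso - vc.evaluate(ts)).max())
    return max(errs)


for cfg in (config.thv_a(), config.thv_b()):
    print(f"--- {cfg.name} ---")
    sk = softgoods.build_skirt(cfg)
    print(f"skirt: {len(sk.verticals)} vertical stations over 120 deg, "
          f"network error {network_error(sk.surface, sk.network):.2e} mm")

    com = softgoods.commissure_build(cfg)
    print(f"commissure: edges at +/-{com.edge_rotation_deg} deg "
          f"(phi_max / 6), lofted from 3 curves")

    surf, curves = softgoods.build_leaflet(cfg)
    fe_z = curves.free_edge.evaluate(np.linspace(0, 1, 9))[:, 2]
    shape = "flat" if np.ptp(fe_z) < 1e-6 else "center-low"
    print(f"leaflet: free edge {shape} "
          f"(z from {fe_z.min():.2f} to {fe_z.max():.2f} mm), "
          f"{len(curves.interior_horizontals)} interior horizontal curve(s)")
    # A flat free edge (short balloon-expandable design) coapts level with
    # the commissures; the center-low design (tall self-expanding) drops the
    # middle of the free edge below the corners.
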