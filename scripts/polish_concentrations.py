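"""Polish the packaged resting concentration vector and freeze it in place.

The resting constraint-based flux solution fixes the direction of every
flux-carrying reaction; a usable resting concentration vector must give each
of those reactions a strictly negative dG' * sign(J) with a comfortable
margin.  dG' is linear in log-concentration, so the polish is a linear
program: maximize the worst-case dissipation margin (capped at 2.5 kJ/mol)
over the species' literature bounds, then minimize the total log-space
deviation from the authored defaults at that margin.  Side pools that carry
no resting flux are analytically equilibrated afterwards, and the final
vector is re-verified exactly before being written back into
``src/fuelswitch/data/network.json`` as the packaged ``conc_default``.

Run after ``build_network.py``:

    python scripts/build_network.py
    python scripts/polish_concentrations.py
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from fuelswitch.cba import solve_timepoint
from fuelswitch.constants import RT
from fuelswitch.kinetics import DEFAULT_CLAMPED, equilibrate_side_pools
from fuelswitch.network import canonical_network_path, load_canonical_network
from fuelswitch.synthetic_data import resting_boundary
from fuelswitch.thermo import delta_g_prime, second_law_violations

# Per-reaction dissipation-margin targets (kJ/mol).  Near-equilibrium steps
# get a small margin, which makes their algebraically assigned activities
# large and gives them bidirectional buffering capacity; the committed,
# physiologically irreversible steps (kinases of upper glycolysis, the
# dehydrogenase complexes, citrate synthase, thiolases, the respiratory
# pumps, ATP hydrolysis) get large margins so that a transient surplus
# throttles them instead of running them backwards (e.g. reverse electron
# transport through Complex 1 flooding the matrix with NADH).
MARGIN_DEFAULT = 0.4
MARGIN_TARGETS = {
    "GLUT": 0.2, "HK": 4.0, "PFK": 4.0, "PK": 4.0,
    "PDH": 4.0, "CS": 4.0, "IDH": 2.0, "AKGDH": 4.0,
    "C1": 3.0, "C34": 8.0, "ATPASE": 20.0, "PPIASE": 10.0,
    "LDH": 1.0, "GPD1": 1.0, "GPD2": 3.0, "ETF": 2.0, "FACS": 4.0,
    **{f"ACAD_C{n}": 1.0 for n in (16, 14, 12, 10, 8, 6, 4)},
    **{f"KAT_C{n}": 4.0 for n in (16, 14, 12, 10, 8, 6, 4)},
}
FIXED = set(DEFAULT_CLAMPED) | {"lac_e"}


def main() -> None:
    net = load_canonical_network()
    bnd = resting_boundary()
    J, _, status = solve_timepoint(net, bnd, lactate_fixed=True, boundary_tolerance=1e-9, leak_fraction=0.15)
    assert status == "optimal", status
    fluxes = dict(zip(net.reaction_ids, J))
    tol = 1e-9 * np.max(np.abs(J))

    free = [s.id for s in net.species if s.id not in FIXED]
    idx = {sid: i for i, sid in enumerate(free)}
    n = len(free)
    defaults = net.default_concentrations()
    ln0 = np.array([np.log(defaults[sid]) for sid in free])
    lb = np.array([np.log(net.get_species(sid).conc_lower) for sid in free])
    ub = np.array([np.log(net.get_species(sid).conc_upper) for sid in free])

    rows, rhs, targets = [], [], []
    for rid, j in fluxes.items():
        if abs(j) <= tol:
            continue
        rxn = net.get_reaction(rid)
        s = np.sign(j)
        row = np.zeros(n + 1)
        const = rxn.dG0_prime
        for sid, coeff in rxn.stoichiometry.items():
            if sid in idx:
                row[idx[sid]] = s * RT * coeff
            else:
                const += RT * coeff * np.log(defaults[sid])
        targets.append(MARGIN_TARGETS.get(rid, MARGIN_DEFAULT))
        row[n] = targets[-1]  # + lambda * target
        rows.append(row)
        rhs.append(-s * const)

    # phase 1: maximize the common achieved fraction lambda of the targets
    c = np.zeros(n + 1)
    c[n] = -1.0
    bounds = [(l, u) for l, u in zip(lb, ub)] + [(0.0, 1.0)]
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds, method="highs")
    assert res.status == 0, res.message
    lam = res.x[n]
    print(f"achievable fraction of margin targets: {lam:.3f}")
    assert lam > 0.5, "resting vector cannot approach the target margins within bounds"
    lam = min(lam * 0.98, 1.0)
    # phase 2: at lambda * targets, stay close to the authored defaults
    nv = 2 * n  # lnc plus L1 helpers
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub2, b_ub2 = [], []
    for row, b, tgt in zip(rows, rhs, targets):
        A_ub2.append(np.concatenate([row[:n], np.zeros(n)]))
        b_ub2.append(b - lam * tgt)
    for i in range(n):  # |lnc - ln0| <= u_i
        r = np.zeros(nv)
        r[i], r[n + i] = 1.0, -1.0
        A_ub2.append(r)
        b_ub2.append(ln0[i])
        r = np.zeros(nv)
        r[i], r[n + i] = -1.0, -1.0
        A_ub2.append(r)
        b_ub2.append(-ln0[i])
    bounds2 = [(l, u) for l, u in zip(lb, ub)] + [(0.0, None)] * n
    res2 = linprog(c2, A_ub=np.array(A_ub2), b_ub=np.array(b_ub2), bounds=bounds2, method="highs")
    assert res2.status == 0, res2.message
    lnc = res2.x[:n]

    conc = dict(defaults)
    for sid, v in zip(free, np.exp(lnc)):
        conc[sid] = float(v)
    conc = equilibrate_side_pools(net, conc)
    bad = second_law_violations(net, conc, fluxes, flux_tol=tol)
    assert not bad, f"polished vector still violates the second law: {bad}"

    dg = dict(zip(net.reaction_ids, delta_g_prime(net, conc)))
    margins = sorted(
        ((rid, -np.sign(j) * dg[rid]) for rid, j in fluxes.items() if abs(j) > tol),
        key=lambda kv: kv[1],
    )
    print("tightest dissipation margins (kJ/mol):")
    for rid, m in margins[:8]:
        print(f"  {rid:10s} {m:7.3f}")

    path = canonical_network_path()
    doc = json.loads(Path(path).read_text())
    for sp in doc["species"]:
        sp["conc_default"] = conc[sp["id"]]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
    print(f"updated conc_default in {path}")


if __name__ == "__main__":
    main()
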