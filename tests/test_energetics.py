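"""Nonbonded pair energies and the subunit/species/ion decomposition,
checked against an independent brute-force double loop with its own
inline energy formulas."""

import math
import warnings

import numpy as np
import pytest

from bilayermech import (BoxedFrame, NonbondedScheme, gen_charged_toy_system,
                         group_pair_energies, ion_lipid_energies, pair_energy,
                         species_decomposition, total_and_partial)

K_COULOMB = 332.0636


# ---------------------------------------------------------------------------
# independent oracle: plain python double loop, formulas written out inline
# ---------------------------------------------------------------------------


def oracle_pair(r, q1, q2, e1, e2, s1, s2, scheme):
    rc, ron = scheme.cutoff, scheme.lj_switch_on
    if r >= rc:
        return 0.0
    if scheme.coulomb_mode == "shifted":
        coul = K_COULOMB * q1 * q2 * (1.0 / r - 1.0 / rc)
    else:
        krf = (scheme.epsilon_rf - 1.0) / ((2.0 * scheme.epsilon_rf + 1.0) * rc**3)
        coul = K_COULOMB * q1 * q2 * (1.0 / r + krf * r * r - (1.0 / rc + krf * rc * rc))
    eps = math.sqrt(e1 * e2)
    sig = 0.5 * (s1 + s2)
    lj = 4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    if r > ron:
        lj *= ((rc**2 - r**2) ** 2 * (rc**2 + 2 * r**2 - 3 * ron**2)) / (rc**2 - ron**2) ** 3
    return coul + lj


def oracle_decomposition(frame, gmap, scheme):
    """O(N²) reference decomposition keyed like the module's cells."""
    cells = {}
    n = frame.n_sites
    for i in range(n):
        for j in range(i + 1, n):
            if frame.molecule[i] == frame.molecule[j]:
                continue
            d = frame.coords[i] - frame.coords[j]
            d -= frame.box * np.floor(d / frame.box + 0.5)
            r = float(np.linalg.norm(d))
            mi = gmap.species[frame.species[i]]
            mj = gmap.species[frame.species[j]]
            e = oracle_pair(
                r, mi.charges[frame.names[i]], mj.charges[frame.names[j]],
                mi.lj_params[frame.names[i]][0], mj.lj_params[frame.names[j]][0],
                mi.lj_params[frame.names[i]][1], mj.lj_params[frame.names[j]][1], scheme,
            )
            ki = (frame.species[i], mi.site_group[frame.names[i]])
            kj = (frame.species[j], mj.site_group[frame.names[j]])
            key = (ki, kj) if ki <= kj else (kj, ki)
            cells[key] = cells.get(key, 0.0) + e
    return cells


# ---------------------------------------------------------------------------
# pair energy
# ---------------------------------------------------------------------------


def test_pair_energy_zero_beyond_cutoff():
    scheme = NonbondedScheme()
    assert pair_energy(13.0, 1.0, -1.0, (0.2, 4.0), (0.2, 4.0), scheme) == 0.0


def test_shifted_coulomb_hand_value():
    scheme = NonbondedScheme(coulomb_mode="shifted")
    e = pair_energy(5.0, 1.0, -1.0, (0.0, 1.0), (0.0, 1.0), scheme)
    assert e == pytest.approx(K_COULOMB * (1 / 5 - 1 / 12) * (-1.0), rel=1e-12)


def test_lj_zero_at_sigma_inside_switch_on():
    scheme = NonbondedScheme()
    e = pair_energy(4.0, 0.0, 0.0, (0.3, 4.0), (0.3, 4.0), scheme)
    assert e == pytest.approx(0.0, abs=1e-14)


def test_overlapping_sites_error():
    with pytest.raises(ValueError):
        pair_energy(0.0, 1.0, 1.0, (0.1, 4.0), (0.1, 4.0), NonbondedScheme())


@pytest.mark.parametrize("mode", ["shifted", "reaction_field"])
def test_pair_energy_continuous_at_cutoff(mode):
    scheme = NonbondedScheme(coulomb_mode=mode)
    for delta in (1e-3, 1e-6, 1e-9):
        e = pair_energy(scheme.cutoff - delta, 0.7, -0.4, (0.2, 5.0), (0.3, 4.0), scheme)
        assert abs(e) < 1e4 * delta + 1e-9


@pytest.mark.parametrize("mode", ["shifted", "reaction_field"])
def test_pair_energy_matches_oracle_along_r(mode):
    scheme = NonbondedScheme(coulomb_mode=mode)
    for r in np.linspace(2.5, 13.0, 40):
        mine = pair_energy(r, 0.6, -0.9, (0.15, 4.2), (0.25, 3.7), scheme)
        ref = oracle_pair(r, 0.6, -0.9, 0.15, 0.25, 4.2, 3.7, scheme)
        assert mine == pytest.approx(ref, rel=1e-12, abs=1e-14)


# ---------------------------------------------------------------------------
# decomposition vs oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["shifted", "reaction_field"])
def test_decomposition_equals_brute_force(mode):
    frame, gmap = gen_charged_toy_system(60, box=40.0, seed=17)
    assert frame.n_sites <= 300
    scheme = NonbondedScheme(coulomb_mode=mode)
    mine = group_pair_energies(frame, gmap, scheme)
    ref = oracle_decomposition(frame, gmap, scheme)
    scale = max(abs(v) for v in ref.values())
    for key in set(mine.cells) | set(ref):
        assert mine.cells.get(key, 0.0) == pytest.approx(
            ref.get(key, 0.0), rel=1e-10, abs=1e-10 * scale)


def test_two_single_site_molecules_single_cell():
    frame, gmap = gen_charged_toy_system(2, box=30.0, seed=3, ion_fraction=1.0)
    # place the two ions within the cutoff of each other
    frame = BoxedFrame(coords=np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 11.0]]),
                       species=frame.species, molecule=frame.molecule,
                       names=frame.names, box=frame.box)
    scheme = NonbondedScheme()
    d = group_pair_energies(frame, gmap, scheme)
    assert len(d.cells) == 1
    ((key, e),) = d.cells.items()
    dr = float(np.linalg.norm(frame.coords[0] - frame.coords[1]
                              - frame.box * np.floor((frame.coords[0] - frame.coords[1]) / frame.box + 0.5)))
    s0, s1 = frame.species
    e_ref = pair_energy(dr, gmap.species[s0].charges[s0], gmap.species[s1].charges[s1],
                        gmap.species[s0].lj_params[s0], gmap.species[s1].lj_params[s1], scheme)
    assert e == pytest.approx(e_ref, rel=1e-12)


def test_null_parameters_give_zero_energy():
    frame, gmap = gen_charged_toy_system(20, box=30.0, seed=5, charge_model="neutral",
                                         ion_fraction=0.0)
    for smap in gmap.species.values():
        smap.lj_params = {k: (0.0, v[1]) for k, v in smap.lj_params.items()}
    d = group_pair_energies(frame, gmap)
    assert all(abs(v) < 1e-300 for v in d.cells.values())


def test_total_and_partial_closure():
    frame, gmap = gen_charged_toy_system(50, box=40.0, seed=23)
    d = group_pair_energies(frame, gmap)
    total, partial = total_and_partial(d)
    assert total == pytest.approx(partial + d.like_group_sum, rel=1e-9)
    # partial re-derived from the oracle skipping like-group pairs
    ref = oracle_decomposition(frame, gmap, NonbondedScheme())
    lip = set(gmap.lipid_species())
    ref_partial = sum(e for ((si, gi), (sj, gj)), e in ref.items()
                      if gi != gj and si in lip and sj in lip)
    assert partial == pytest.approx(ref_partial, rel=1e-10)


def test_pure_like_group_cell_has_zero_partial():
    frame, gmap = gen_charged_toy_system(2, box=30.0, seed=11, ion_fraction=0.0)
    # keep only the head sites: every remaining pair is head–head
    keep = np.array([g == "head" for g in
                     (gmap.species[s].site_group[n] for s, n in zip(frame.species, frame.names))])
    sub = BoxedFrame(coords=frame.coords[keep], species=frame.species[keep],
                     molecule=frame.molecule[keep], names=frame.names[keep], box=frame.box)
    d = group_pair_energies(sub, gmap)
    total, partial = total_and_partial(d)
    assert partial == 0.0
    assert total == pytest.approx(d.like_group_sum)


def test_species_decomposition_sums_to_total():
    frame, gmap = gen_charged_toy_system(60, box=40.0, seed=29)
    d = group_pair_energies(frame, gmap)
    by = species_decomposition(frame, gmap)
    assert sum(v["total"] for v in by.values()) == pytest.approx(d.total, rel=1e-9)
    assert sum(v["partial"] for v in by.values()) == pytest.approx(d.partial, rel=1e-9)


def test_species_relabeling_swaps_components():
    frame, gmap = gen_charged_toy_system(40, box=40.0, seed=31, ion_fraction=0.0)
    by = species_decomposition(frame, gmap)
    swapped_species = np.array(
        [{"LIPA": "LIPB", "LIPB": "LIPA"}[s] for s in frame.species], dtype=object)
    # swap the species labels and re-key the parameter tables to match, so the
    # physics (parameters at each site) is unchanged while the labels flip
    g2 = type(gmap)(species={"LIPA": gmap.species["LIPB"], "LIPB": gmap.species["LIPA"],
                             "NA": gmap.species["NA"], "CL": gmap.species["CL"]})
    f2 = BoxedFrame(coords=frame.coords, species=swapped_species, molecule=frame.molecule,
                    names=frame.names, box=frame.box)
    by2 = species_decomposition(f2, g2)
    assert by2[("LIPA", "LIPA")]["total"] == pytest.approx(by[("LIPB", "LIPB")]["total"], rel=1e-12)
    assert by2[("LIPB", "LIPB")]["total"] == pytest.approx(by[("LIPA", "LIPA")]["total"], rel=1e-12)
    assert by2[("LIPA", "LIPB")]["total"] == pytest.approx(by[("LIPA", "LIPB")]["total"], rel=1e-12)


def test_energy_invariant_under_translation_and_mol_permutation():
    frame, gmap = gen_charged_toy_system(40, box=40.0, seed=37)
    d0 = group_pair_energies(frame, gmap)
    shifted = BoxedFrame(coords=frame.coords + np.array([5.0, -17.0, 3.3]),
                         species=frame.species, molecule=frame.molecule,
                         names=frame.names, box=frame.box)
    d1 = group_pair_energies(shifted, gmap)
    assert d1.total == pytest.approx(d0.total, rel=1e-9)
    perm = {m: len(np.unique(frame.molecule)) - 1 - m for m in np.unique(frame.molecule)}
    relabeled = BoxedFrame(coords=frame.coords, species=frame.species,
                           molecule=np.array([perm[m] for m in frame.molecule]),
                           names=frame.names, box=frame.box)
    d2 = group_pair_energies(relabeled, gmap)
    assert d2.total == pytest.approx(d0.total, rel=1e-12)


# ---------------------------------------------------------------------------
# ion–lipid energies
# ---------------------------------------------------------------------------


def _na_phosphate_frame(dr=5.0):
    from bilayermech import GroupMap, SpeciesMap

    gmap = GroupMap(species={
        "LIP": SpeciesMap(site_group={"H": "head", "P": "phosphate"},
                          phosphorus_site="P",
                          charges={"H": 0.0, "P": -1.0},
                          lj_params={"H": (0.0, 1.0), "P": (0.0, 1.0)}),
        "NA": SpeciesMap(site_group={"NA": "ion"}, charges={"NA": 1.0},
                         lj_params={"NA": (0.0, 1.0)}),
    })
    frame = BoxedFrame(
        coords=np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 30.0], [10.0 + dr, 10.0, 10.0]]),
        species=np.array(["LIP", "LIP", "NA"], dtype=object),
        molecule=np.array([0, 0, 1]),
        names=np.array(["P", "H", "NA"], dtype=object),
        box=np.array([40.0, 40.0, 60.0]),
    )
    return frame, gmap


def test_ion_phosphate_hand_value():
    frame, gmap = _na_phosphate_frame(dr=5.0)
    head, phos = ion_lipid_energies(frame, gmap, "LIP")
    assert phos == pytest.approx(K_COULOMB * (1 / 5 - 1 / 12) * (-1.0), rel=1e-12)
    assert head == 0.0  # head site is neutral with no LJ: a bare-hydrogen-like headgroup


def test_ions_beyond_cutoff_contribute_nothing():
    frame, gmap = _na_phosphate_frame(dr=15.0)
    assert ion_lipid_energies(frame, gmap, "LIP") == (0.0, 0.0)


def test_no_ions_warns_and_returns_zero():
    frame, gmap = gen_charged_toy_system(10, box=30.0, seed=41, ion_fraction=0.0)
    with pytest.warns(UserWarning, match="no ion"):
        assert ion_lipid_energies(frame, gmap, "LIPA") == (0.0, 0.0)


def test_ion_energies_match_oracle():
    frame, gmap = gen_charged_toy_system(60, box=40.0, seed=43, ion_fraction=0.4)
    scheme = NonbondedScheme(coulomb_mode="reaction_field")
    head, phos = ion_lipid_energies(frame, gmap, "LIPB", scheme)
    ref = oracle_decomposition(frame, gmap, scheme)
    ions = {"NA", "CL"}
    ref_head = sum(e for ((si, gi), (sj, gj)), e in ref.items()
                   if (si in ions and (sj, gj) == ("LIPB", "head"))
                   or (sj in ions and (si, gi) == ("LIPB", "head")))
    ref_phos = sum(e for ((si, gi), (sj, gj)), e in ref.items()
                   if (si in ions and (sj, gj) == ("LIPB", "phosphate"))
                   or (sj in ions and (si, gi) == ("LIPB", "phosphate")))
    assert head == pytest.approx(ref_head, rel=1e-10)
    assert phos == pytest.approx(ref_phos, rel=1e-10)
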