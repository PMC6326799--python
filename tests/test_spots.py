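"""Spot detection, molecule grouping, classification and orientation."""

from itertools import combinations

import numpy as np
import pytest

from nucfish.images import ImageStack
from nucfish.profiles import DapiCoordinate, dapi_centroid, nucleus_mask
from nucfish.spots import (
    Molecule,
    Spot,
    classify_molecule_species,
    detect_spots,
    group_spots_to_molecules,
    localize_molecule,
    molecules_from_truth,
    orientation_analysis,
    per_cell_counts,
)
from nucfish.synthetic import OpticsParams, generate_cell_scene, render_image


def spot(ch, z, y, x):
    return Spot(ch, np.array([z, y, x], dtype=float), 100.0)


class TestDetection:
    def test_blank_channel_empty(self):
        stack = ImageStack(np.full((1, 8, 16, 16), 5.0), (0.1, 0.1, 0.1), ["red"])
        assert detect_spots(stack, "red") == []

    def test_single_noise_free_spot_subvoxel_accuracy(self):
        scene = generate_cell_scene({("single_probe", "cytoplasm"): 1}, seed=1)
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        spots = detect_spots(stack, "red")
        assert len(spots) == 1
        truth = scene.molecules[0].probe_positions["red"]
        assert np.linalg.norm(spots[0].position - truth) < 0.05  # half a voxel

    def test_poisson_recovery_count_and_rms(self):
        errors, n_ok = [], 0
        for seed in range(6):
            scene = generate_cell_scene(
                {("single_probe", "cytoplasm"): 4}, seed=30 + seed
            )
            stack = render_image(scene, OpticsParams(noise_model="poisson"), seed=seed)
            spots = detect_spots(stack, "red")
            truth = [m.probe_positions["red"] for m in scene.molecules]
            n_ok += len(spots) == len(truth)
            for t in truth:
                d = min(np.linalg.norm(s.position - t) for s in spots)
                errors.append(d)
        assert n_ok == 6
        assert np.sqrt(np.mean(np.square(errors))) < 0.1  # 1 voxel RMS


class TestGrouping:
    def test_triplet_within_radius_forms_one_molecule(self):
        spots = [spot("red", 1, 1, 1), spot("ir", 1, 1.1, 1), spot("green", 1, 1, 1.1)]
        mols = group_spots_to_molecules(spots)
        assert len(mols) == 1 and mols[0].channels == {"red", "ir", "green"}

    def test_distance_cap_splits_far_spot(self):
        spots = [spot("red", 1, 1, 1), spot("ir", 1, 1.3, 1), spot("green", 1, 2.2, 1)]
        mols = group_spots_to_molecules(spots, pairing_radius=0.5)
        channel_sets = sorted(tuple(sorted(m.channels)) for m in mols)
        assert channel_sets == [("green",), ("ir", "red")]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        spots = [
            spot(ch, *rng.uniform(0, 4, 3))
            for ch in ("red", "ir", "green") for _ in range(4)
        ]
        ref = group_spots_to_molecules(spots)
        for _ in range(5):
            perm = [spots[i] for i in rng.permutation(len(spots))]
            got = group_spots_to_molecules(perm)
            key = lambda ms: sorted(
                sorted((s.channel, tuple(s.position)) for s in m.spots.values())
                for m in ms
            )
            assert key(got) == key(ref)

    @staticmethod
    def _oracle(spots, cap):
        """Exhaustive grouping: maximize linked spots, then minimize the sum
        of intra-molecule pairwise distances."""
        best = None

        def ok(group):
            chans = [spots[i].channel for i in group]
            if len(set(chans)) != len(chans):
                return False
            return all(
                np.linalg.norm(spots[i].position - spots[j].position) <= cap
                for i, j in combinations(group, 2)
            )

        def cost(partition):
            links = sum(len(g) - 1 for g in partition)
            dist = sum(
                np.linalg.norm(spots[i].position - spots[j].position)
                for g in partition for i, j in combinations(g, 2)
            )
            return (-links, dist)

        def recurse(i, partition):
            nonlocal best
            if i == len(spots):
                c = cost(partition)
                if best is None or c < best[0]:
                    best = (c, [tuple(sorted(g)) for g in partition])
                return
            for g in partition:
                if ok(g + [i]):
                    g.append(i)
                    recurse(i + 1, partition)
                    g.pop()
            partition.append([i])
            recurse(i + 1, partition)
            partition.pop()

        recurse(0, [])
        return sorted(best[1])

    def test_matches_exhaustive_assignment_on_scene_density_fields(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            spots = []
            # a few molecule-like clusters plus strays, scene-like spacing
            for _ in range(2):
                anchor = rng.uniform(1, 4, 3)
                for ch in ("red", "ir", "green"):
                    spots.append(Spot(ch, anchor + rng.normal(0, 0.08, 3), 1.0))
            for ch in ("red", "green"):
                spots.append(Spot(ch, rng.uniform(1, 4, 3), 1.0))
            got = group_spots_to_molecules(spots, 0.5)
            index_of = {id(s): i for i, s in enumerate(spots)}
            got_key = sorted(
                tuple(sorted(index_of[id(s)] for s in m.spots.values())) for m in got
            )
            assert got_key == self._oracle(spots, 0.5)


class TestSpeciesClassification:
    @pytest.mark.parametrize(
        "channels,expected",
        [
            (("red", "ir", "green"), "intact"),
            (("red", "ir"), "five_prime_part"),
            (("ir", "green"), "three_prime_part"),
            (("red",), "single_probe"),
            (("red", "green"), "intact"),  # both ends, no internal probe
        ],
    )
    def test_single_gene_combinations(self, probe_map, channels, expected):
        mol = Molecule(spots={ch: spot(ch, 1, 1, 1) for ch in channels})
        assert classify_molecule_species(mol, probe_map) == expected

    def test_two_gene_combination_is_readthrough(self):
        pm = {"ir": ("geneB", "internal"), "green": ("geneA", "three_prime")}
        mol = Molecule(spots={ch: spot(ch, 1, 1, 1) for ch in ("ir", "green")})
        assert classify_molecule_species(mol, pm) == "readthrough"

    def test_unmapped_channel_errors(self, probe_map):
        mol = Molecule(spots={"magenta": spot("magenta", 1, 1, 1)})
        with pytest.raises(KeyError):
            classify_molecule_species(mol, probe_map)


class TestLocalization:
    def _molecule_with_coords(self, coords):
        mol = Molecule(spots={f"ch{i}": spot(f"ch{i}", 1, 1, 1) for i in range(len(coords))})
        mol.coords = {
            f"ch{i}": DapiCoordinate(percent=p, side=s)
            for i, (p, s) in enumerate(coords)
        }
        return mol

    @pytest.mark.parametrize(
        "coords,expected",
        [
            ([(5.0, "cytoplasmic"), (8.0, "cytoplasmic")], "cytoplasm"),
            ([(40.0, "cytoplasmic")], "nuclear_periphery"),
            ([(80.0, "cytoplasmic"), (95.0, "cytoplasmic")], "nucleus"),
            ([(10.0, "cytoplasmic"), (80.0, "cytoplasmic")], "nuclear_periphery"),
            ([(66.6, "cytoplasmic")], "nuclear_periphery"),  # inclusive edges
            ([(40.0, "nucleolar")], "nucleus"),  # band applies on cyto flank only
            ([(5.0, "cytoplasmic"), (95.0, "nucleolar")], "nucleus"),
        ],
    )
    def test_band_rule(self, coords, expected):
        """The periphery band rule (any signal in 10-66.6 on the cytoplasmic
        flank) with cytoplasm only when every signal is below 10."""
        from nucfish.spots import classify_location_from_coords

        mol = self._molecule_with_coords(coords)
        assert classify_location_from_coords(mol.coords) == expected

    def test_localize_on_rendered_scene_matches_truth(self, clean_scene, clean_stack):
        centroid = dapi_centroid(clean_stack)
        mols = molecules_from_truth(clean_scene)
        rename = {"periphery": "nuclear_periphery"}
        for mol, gt in zip(mols, clean_scene.molecules):
            loc = localize_molecule(mol, clean_stack, centroid)
            assert loc == rename.get(gt.true_location, gt.true_location)

    def test_partition_exhaustive_and_exclusive(self, clean_scene, clean_stack):
        centroid = dapi_centroid(clean_stack)
        mols = molecules_from_truth(clean_scene)
        locs = [localize_molecule(m, clean_stack, centroid) for m in mols]
        assert all(
            l in ("nucleus", "nuclear_periphery", "cytoplasm", "unclassifiable")
            for l in locs
        )


class TestOrientation:
    def test_all_oriented_gives_fraction_one(self):
        scene = generate_cell_scene(
            {("five_prime_part", "periphery"): 6}, orientation_fraction=1.0, seed=40
        )
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        centroid = dapi_centroid(stack)
        mols = molecules_from_truth(scene)
        for m in mols:
            localize_molecule(m, stack, centroid)
        res = orientation_analysis(mols, nucleus_mask(stack), stack.voxel_size)
        assert res.n_eligible == 6 and res.fraction == 1.0

    def test_non_intersecting_pairs_excluded(self):
        scene = generate_cell_scene(
            {("five_prime_part", "periphery"): 3, ("five_prime_part", "cytoplasm"): 4},
            orientation_fraction=1.0, seed=41,
        )
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        centroid = dapi_centroid(stack)
        mols = molecules_from_truth(scene)
        for m in mols:
            localize_molecule(m, stack, centroid)
        res = orientation_analysis(mols, nucleus_mask(stack), stack.voxel_size)
        assert res.n_eligible == 3  # cytoplasmic pairs never cross the nucleus

    def test_zero_eligible_fraction_undefined(self):
        res = orientation_analysis([], np.zeros((4, 4, 4), bool), (0.1, 0.1, 0.1))
        assert res.n_eligible == 0 and res.fraction is None


class TestPerCellCounts:
    def _mol(self, species, location):
        m = Molecule(spots={"ir": spot("ir", 1, 1, 1)})
        m.species, m.location = species, location
        return m

    def test_single_cell_single_category(self):
        mols = [self._mol("intact", "cytoplasm") for _ in range(10)]
        table, summary = per_cell_counts({"cell0": mols})
        assert table.loc["cell0", ("intact", "cytoplasm")] == 10
        assert table.to_numpy().sum() == 10

    def test_empty_input_all_zero(self):
        table, _ = per_cell_counts({"cell0": []})
        assert table.shape[1] == 0

    def test_unclassifiable_excluded_from_totals(self):
        mols = [self._mol("intact", "cytoplasm"), self._mol("intact", "unclassifiable")]
        table, _ = per_cell_counts({"c": mols})
        assert table.to_numpy().sum() == 1

    def test_mean_and_sd_across_cells(self):
        cells = {
            "a": [self._mol("intact", "nucleus")] * 2,
            "b": [self._mol("intact", "nucleus")] * 4,
        }
        _, summary = per_cell_counts(cells)
        row = summary.loc[("intact", "nucleus")]
        assert row["mean"] == 3.0 and row["sd"] == pytest.approx(np.sqrt(2))


class TestEndToEndRecovery:
    def test_noise_free_counts_exact(self, default_counts, probe_map):
        from collections import Counter

        for seed in (50, 51, 52):
            scene = generate_cell_scene(default_counts, 0.81, seed=seed)
            stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
            spots = []
            for ch in ("red", "ir", "green"):
                spots += detect_spots(stack, ch)
            mols = group_spots_to_molecules(spots)
            centroid = dapi_centroid(stack)
            tally = Counter()
            for m in mols:
                sp = classify_molecule_species(m, probe_map)
                loc = localize_molecule(m, stack, centroid)
                tally[(sp, loc.replace("nuclear_periphery", "periphery"))] += 1
            assert tally == Counter(
                {(m.species, m.true_location): 0 for m in scene.molecules}
            ) + Counter((m.species, m.true_location) for m in scene.molecules)
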