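"""Scene assembly: tubes, backbone, ribbons, rails, and the full composition."""

import numpy as np
import pytest

from pathflow import (
    RenderConfig,
    assemble_scene,
    build_backbone,
    build_ladder_rails,
    build_pathline_tube,
    build_trailing_membranes,
    connected_components,
    fit_natural_cubic,
    scene_census,
    scene_to_json,
    select_atoms,
    temporal_color,
)
from pathflow.scene_build import Cylinder, Mesh, Scene, Sphere
from conftest import dense_natural_eval, dense_natural_moments


def _splines(trajectory):
    return [fit_natural_cubic(trajectory.positions[k])
            for k in range(trajectory.n_atoms)]


class TestPathlineTube:
    def test_mesh_census_formula(self, rng, census_config):
        sp = fit_natural_cubic(rng.normal(size=(3, 3)) * 5)
        tube = build_pathline_tube(sp, census_config)
        assert len(tube.vertices) == ((3 - 1) * 4 + 1) * 8 == 72
        assert len(tube.faces) == (3 - 1) * 4 * 8 * 2 == 128

    def test_straight_spline_rings_are_collinear_and_normal(self, census_config):
        direction = np.array([1.0, 0.0, 0.0])
        sp = fit_natural_cubic(np.outer(np.arange(4.0), direction) * 3.8)
        tube = build_pathline_tube(sp, census_config)
        r = census_config.ring_vertices
        rings = tube.vertices.reshape(-1, r, 3)
        centers = rings.mean(axis=1)
        spread = centers - centers[0]
        cross = np.cross(spread[1:], direction)
        assert np.max(np.abs(cross)) < 1e-9  # centers on the line
        for ring, center in zip(rings, centers):
            axial = (ring - center) @ direction
            assert np.max(np.abs(axial)) < 1e-9  # ring plane normal = line dir

    def test_temporal_colors_at_tube_ends(self, rng, census_config):
        sp = fit_natural_cubic(rng.normal(size=(5, 3)) * 4)
        tube = build_pathline_tube(sp, census_config)
        r = census_config.ring_vertices
        assert np.allclose(tube.colors[:r], (0.0, 0.0, 1.0))    # blue start
        assert np.allclose(tube.colors[-r:], (1.0, 1.0, 0.0))   # yellow end

    def test_no_color_drift_through_assembly(self, rng, census_config):
        """Every tube vertex carries exactly the temporal color of its sample."""
        sp = fit_natural_cubic(rng.normal(size=(4, 3)) * 4)
        tube = build_pathline_tube(sp, census_config)
        params, _ = sp.sample(census_config.segments_per_interval)
        r = census_config.ring_vertices
        for i, t in enumerate(params):
            expected = temporal_color(t / sp.t_max)
            assert np.allclose(tube.colors[i * r:(i + 1) * r], expected)


class TestBackbone:
    def test_six_atoms_make_six_spheres_five_links(self, hinge_trajectory):
        prims = build_backbone(hinge_trajectory, _splines(hinge_trajectory),
                               RenderConfig())
        spheres = [p for p in prims if isinstance(p, Sphere)]
        cyls = [p for p in prims if isinstance(p, Cylinder)]
        assert len(spheres) == 6 and len(cyls) == 5

    def test_single_atom_backbone(self):
        from pathflow.pdb_io import Trajectory
        from pathflow.pdb_io import AtomRecord
        meta = [AtomRecord(serial=1, name="CA", resname="GLY", chain="A",
                           resseq=1, coords=(0, 0, 0))]
        traj = Trajectory(atom_meta=meta,
                          positions=np.linspace(0, 5, 4).reshape(1, 4, 1)
                          * np.ones(3))
        prims = build_backbone(traj, _splines(traj), RenderConfig())
        assert len([p for p in prims if isinstance(p, Sphere)]) == 1
        assert len([p for p in prims if isinstance(p, Cylinder)]) == 0

    def test_interpolated_backbone_matches_dense_oracle(self, hinge_trajectory):
        """Backbone at t=1.5 sits on the spline, per the dense-solve oracle."""
        cfg = RenderConfig(backbone_time=1.5)
        prims = build_backbone(hinge_trajectory, _splines(hinge_trajectory), cfg)
        spheres = [p for p in prims if isinstance(p, Sphere)]
        for k, s in enumerate(spheres):
            pts = hinge_trajectory.positions[k]
            oracle = dense_natural_eval(pts, dense_natural_moments(pts), 1.5)
            assert np.max(np.abs(s.center - oracle)) < 1e-9

    def test_snap_rounds_to_nearest_pose(self, hinge_trajectory):
        cfg = RenderConfig(backbone_time=3.4, backbone_snap=True)
        prims = build_backbone(hinge_trajectory, _splines(hinge_trajectory), cfg)
        centers = np.array([p.center for p in prims if isinstance(p, Sphere)])
        assert np.allclose(centers, hinge_trajectory.positions[:, 3, :], atol=1e-9)

    def test_split_chains_drops_inter_chain_link(self):
        """Two helices (chains A and B): the A-B link exists only when
        chain splitting is off."""
        from pathflow import generate_helix_rotation, select_atoms

        traj = select_atoms(generate_helix_rotation(n_res=3, n_poses=5))
        joined = build_backbone(traj, _splines(traj), RenderConfig())
        split = build_backbone(traj, _splines(traj),
                               RenderConfig(split_chains=True))
        n_cyl = lambda prims: len([p for p in prims if isinstance(p, Cylinder)])
        assert n_cyl(joined) == traj.n_atoms - 1
        assert n_cyl(split) == traj.n_atoms - 2

    def test_backbone_time_out_of_range(self, hinge_trajectory):
        cfg = RenderConfig(backbone_time=12.0)
        with pytest.raises(ValueError):
            build_backbone(hinge_trajectory, _splines(hinge_trajectory), cfg)


class TestMembranes:
    @pytest.mark.parametrize("k, expected", [(6, 3), (2, 1), (1, 0), (5, 2)])
    def test_disjoint_pairing_count(self, rng, k, expected):
        splines = [fit_natural_cubic(rng.normal(size=(6, 3)) + 10 * i)
                   for i in range(k)]
        ribbons = build_trailing_membranes(splines, RenderConfig())
        assert len(ribbons) == expected

    def test_fade_contract_at_edges(self, rng):
        cfg = RenderConfig(alpha_max=0.6, ribbon_fade_fraction=0.4)
        splines = [fit_natural_cubic(rng.normal(size=(6, 3)) + 10 * i)
                   for i in range(2)]
        (ribbon,) = build_trailing_membranes(splines, cfg)
        # vertices are interleaved pairs along increasing t; last two are at t_b
        assert np.allclose(ribbon.opacity[-2:], 0.6)
        assert np.allclose(ribbon.opacity[:2], 0.0, atol=1e-12)
        assert np.all(np.diff(ribbon.opacity[::2]) >= -1e-12)


class TestLadderRails:
    def test_rung_count_formula(self, rng):
        splines = [fit_natural_cubic(rng.normal(size=(5, 3)) + 10 * i)
                   for i in range(3)]
        rails = build_ladder_rails(splines, RenderConfig(ladder_rails=True))
        assert len(rails) == (3 - 1) * 5 == 10

    def test_single_pathline_has_no_rails(self, rng):
        splines = [fit_natural_cubic(rng.normal(size=(5, 3)))]
        assert build_ladder_rails(splines, RenderConfig()) == []

    def test_rails_connect_everything(self, hinge_trajectory):
        """Union-find over touching primitives: tubes + rails + backbone form
        a single connected component."""
        cfg = RenderConfig(segments_per_interval=4, ring_vertices=8,
                           ribbons=False, ladder_rails=True)
        scene = assemble_scene(hinge_trajectory, cfg)
        comps = connected_components(scene.primitives)
        assert len(comps) == 1

    def test_tubes_alone_are_disconnected(self, hinge_trajectory):
        cfg = RenderConfig(segments_per_interval=4, ribbons=False,
                           ladder_rails=False)
        scene = assemble_scene(hinge_trajectory, cfg)
        tubes = [p for p in scene.primitives if getattr(p, "kind", "") == "tube"]
        assert len(connected_components(tubes)) > 1


class TestAssembleScene:
    def test_census_is_sum_of_component_formulas(self, hinge_trajectory,
                                                 census_config):
        K, M = 6, 10
        s, r = 4, 8
        cfg = census_config.model_copy(update={"ladder_rails": True})
        scene = assemble_scene(hinge_trajectory, cfg)
        kinds = scene_census(scene)["by_kind"]
        assert kinds["tube"] == K
        assert kinds["backbone_sphere"] == K
        assert kinds["backbone_cylinder"] == K - 1
        assert kinds["membrane"] == K // 2
        assert kinds["rail"] == (K - 1) * M
        tubes = [p for p in scene.primitives if p.kind == "tube"]
        assert all(len(t.vertices) == ((M - 1) * s + 1) * r == 296 for t in tubes)

    def test_features_off_leaves_tubes_and_backbone(self, hinge_trajectory):
        cfg = RenderConfig(ribbons=False, ladder_rails=False)
        kinds = scene_census(assemble_scene(hinge_trajectory, cfg))["by_kind"]
        assert set(kinds) == {"tube", "backbone_sphere", "backbone_cylinder"}

    def test_deterministic_serialization(self, hinge_trajectory, census_config):
        a = scene_to_json(assemble_scene(hinge_trajectory, census_config))
        b = scene_to_json(assemble_scene(hinge_trajectory, census_config))
        assert a == b

    def test_bounding_box_contains_control_points(self, hinge_trajectory):
        scene = assemble_scene(hinge_trajectory, RenderConfig())
        verts = np.concatenate([p.vertices for p in scene.primitives
                                if isinstance(p, Mesh)])
        lo, hi = verts.min(axis=0), verts.max(axis=0)
        pts = hinge_trajectory.positions.reshape(-1, 3)
        margin = 0.5  # tube radius + tessellation slack
        assert np.all(pts >= lo - margin) and np.all(pts <= hi + margin)

    def test_mesh_faces_are_non_degenerate(self, census_config):
        """Every mesh face has positive area when all pathlines move.

        (Stationary pathlines are degenerate inputs: their tubes and ribbons
        collapse by construction, so the check uses the helix fixture, where
        every atom traces a real arc.)
        """
        from pathflow import generate_helix_rotation, select_atoms

        traj = select_atoms(generate_helix_rotation(n_res=4, n_poses=6),
                            name_filter={"CA", "CG"})
        scene = assemble_scene(traj, census_config)
        for p in scene.primitives:
            if not isinstance(p, Mesh):
                continue
            v = p.vertices
            tri = v[p.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
            assert np.all(areas > 1e-12)

    def test_camera_frames_bounding_sphere(self, hinge_trajectory):
        scene = assemble_scene(hinge_trajectory, RenderConfig())
        pts = hinge_trajectory.positions.reshape(-1, 3)
        center = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
        radius = 0.5 * np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        assert np.allclose(scene.camera_look_at, center)
        assert np.linalg.norm(scene.camera_position - center) == pytest.approx(
            2.5 * radius)


class TestPrimitiveValidation:
    def test_sphere_radius_positive(self):
        with pytest.raises(ValueError):
            Sphere(center=np.zeros(3), radius=0.0, rgb=(1, 0, 0))

    def test_cylinder_endpoints_distinct(self):
        with pytest.raises(ValueError):
            Cylinder(end1=np.zeros(3), end2=np.zeros(3), radius=0.5,
                     rgb_end1=(1, 0, 0), rgb_end2=(0, 0, 1))

    def test_mesh_face_indices_validated(self):
        with pytest.raises(ValueError):
            Mesh(vertices=np.zeros((3, 3)), faces=np.array([[0, 1, 5]]),
                 colors=np.zeros((3, 3)), opacity=np.ones(3))

    def test_scene_needs_light_and_up(self):
        with pytest.raises(ValueError):
            Scene(primitives=[], camera_position=np.zeros(3),
                  camera_look_at=np.ones(3), camera_up=np.zeros(3),
                  lights=[(np.ones(3), (1, 1, 1))])
        with pytest.raises(ValueError):
            Scene(primitives=[], camera_position=np.zeros(3),
                  camera_look_at=np.ones(3), camera_up=np.array([0, 1, 0]),
                  lights=[])
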