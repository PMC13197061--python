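import numpy as np
import pytest

from icodiff.geometry import (
    build_icosphere,
    make_parcellation,
    n_vertices_at_order,
    pool,
    resample_to_icosphere,
    unpool,
)


@pytest.mark.parametrize("order", range(5))
def test_counts_euler_and_valence(order):
    ico = build_icosphere(order)
    assert ico.n_vertices == 10 * 4**order + 2
    assert ico.n_faces == 20 * 4**order
    assert ico.n_edges == 30 * 4**order
    assert ico.n_vertices - ico.n_edges + ico.n_faces == 2
    assert np.allclose(np.linalg.norm(ico.vertices, axis=1), 1.0, atol=1e-12)
    assert (ico.valence == 5).sum() == 12
    assert np.all((ico.valence == 5) | (ico.valence == 6))
    # the 12 pentagons are the base icosahedron vertices
    assert np.all(np.flatnonzero(ico.valence == 5) == np.arange(12))


def test_vertex_prefix_property():
    spheres = [build_icosphere(k) for k in range(5)]
    for k in range(1, 5):
        n_prev = spheres[k - 1].n_vertices
        assert np.array_equal(spheres[k].vertices[:n_prev], spheres[k - 1].vertices)


def test_construction_is_deterministic():
    a, b = build_icosphere(3), build_icosphere(3)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)
    assert np.array_equal(a.neighbors, b.neighbors)


def test_order_bounds():
    with pytest.raises(ValueError):
        build_icosphere(-1)
    with pytest.raises(ValueError):
        build_icosphere(9)


def _face_rings(ico):
    """Brute-force cyclic 1-rings by walking the faces around each vertex."""
    from collections import defaultdict

    succ = defaultdict(dict)
    for a, b, c in ico.faces:
        succ[a][b] = c
        succ[b][c] = a
        succ[c][a] = b
    rings = []
    for v in range(ico.n_vertices):
        nxt = succ[v]
        start = min(nxt)
        ring = [start]
        while True:
            n = nxt[ring[-1]]
            if n == start:
                break
            ring.append(n)
        rings.append(ring)
    return rings


def test_neighbor_table_matches_face_adjacency_oracle(ico2):
    rings = _face_rings(ico2)
    for v in range(ico2.n_vertices):
        k = ico2.valence[v]
        mine = list(ico2.neighbors[v][:k])
        oracle = rings[v]
        assert sorted(mine) == sorted(oracle)
        assert len(set(mine)) == k and v not in mine
        # same cyclic sequence up to rotation and orientation
        doubled = oracle + oracle
        fwd = any(doubled[i : i + k] == mine for i in range(k))
        rev = any(doubled[i : i + k] == mine[::-1] for i in range(k))
        assert fwd or rev


def test_neighbor_symmetry(ico3):
    for v in range(ico3.n_vertices):
        for n in ico3.neighbors[v][: ico3.valence[v]]:
            assert v in ico3.neighbors[n][: ico3.valence[n]]


def test_pentagon_pad_is_self(ico2):
    for v in np.flatnonzero(ico2.valence == 5):
        row = ico2.neighbors[v]
        assert row[5] == v
        assert len(set(row[:5])) == 5 and v not in row[:5]


def test_pool_keeps_prefix_and_unpool_zero_pads(rng):
    x = rng.standard_normal((3, 162, 2))
    up = unpool(x)
    assert up.shape == (3, 642, 2)
    assert np.array_equal(up[:, :162], x)
    assert np.all(up[:, 162:] == 0)
    assert up.sum() == pytest.approx(x.sum())
    assert np.array_equal(pool(up), x)


def test_pool_of_constant_map_is_constant():
    c = np.full((n_vertices_at_order(3), 1), 2.5)
    assert np.all(pool(c) == 2.5)


def test_pool_shape_validation():
    with pytest.raises(ValueError):
        pool(np.zeros((3, 100, 2)))
    with pytest.raises(ValueError):
        pool(np.zeros((3, 12, 2)))  # below order 0


def test_resample_identity_and_constant(ico2, rng):
    x = rng.standard_normal(ico2.n_vertices)
    out = resample_to_icosphere(x, ico2.vertices, ico2.faces, ico2, "barycentric")
    assert np.allclose(out, x, atol=1e-10)
    const = np.full(ico2.n_vertices, 3.0)
    out = resample_to_icosphere(const, ico2.vertices, ico2.faces, ico2, "barycentric")
    assert np.allclose(out, 3.0, atol=1e-10)


def test_resample_linear_field_beats_nearest(ico3):
    ico4 = build_icosphere(4)
    a = np.array([0.3, -0.7, 0.5])
    f_src = ico3.vertices @ a
    f_true = ico4.vertices @ a
    bary = resample_to_icosphere(f_src, ico3.vertices, ico3.faces, ico4, "barycentric")
    near = resample_to_icosphere(f_src, ico3.vertices, ico3.faces, ico4, "nearest")
    assert np.abs(bary - f_true).max() < np.abs(near - f_true).max()


def test_parcellation_partitions_sphere():
    ico4 = build_icosphere(4)
    parc = make_parcellation(ico4, 34, seed=3)
    assert parc.labels.shape == (2562,)
    counts = np.bincount(parc.labels, minlength=34)
    assert np.all(counts > 0)
    assert counts.sum() == 2562


def test_parcellation_determinism_and_edges(ico2):
    a = make_parcellation(ico2, 7, seed=5)
    b = make_parcellation(ico2, 7, seed=5)
    assert np.array_equal(a.labels, b.labels)
    assert np.all(make_parcellation(ico2, 1, seed=0).labels == 0)
    with pytest.raises(ValueError):
        make_parcellation(ico2, 0)
    with pytest.raises(ValueError):
        make_parcellation(ico2, ico2.n_vertices + 1)


def test_icosahedral_symmetries_permute_mesh(ico2):
    from icodiff.geometry import icosahedral_symmetries

    perms = icosahedral_symmetries(ico2)
    assert perms.shape == (60, ico2.n_vertices)
    assert len({p.tobytes() for p in perms}) == 60
    assert any(np.array_equal(p, np.arange(ico2.n_vertices)) for p in perms)
    rings = [set(ico2.neighbors[i][: ico2.valence[i]]) for i in range(ico2.n_vertices)]
    P = perms[13]
    for i in range(ico2.n_vertices):
        assert {P[j] for j in rings[i]} == rings[P[i]]  # adjacency-preserving
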