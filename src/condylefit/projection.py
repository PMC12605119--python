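"""Projection of feature curves onto the bone, segmentation, reconstruction.

The three operations implement the pipeline's third step: contour feature
curves are cast onto the femoral condyle mesh, the outermost projected curves
(closed with geodesic connectors) bound a region that is cut out of the bone
surface, and the cut-out is reconstructed (hole filling plus boundary-
preserving Laplacian smoothing) into the prosthesis attachment surface.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._geom import closest_points_on_mesh, ray_mesh_intersections
from .errors import (
    EmptySelectionError,
    OpenContourError,
    ProjectionFailedError,
    ReconstructionError,
    SeedRequiredError,
)
from .surface import FeatureCurve

log = logging.getLogger(__name__)


def project_curve(
    curve: FeatureCurve,
    femur: trimesh.Trimesh,
    direction,
    max_miss_fraction: float = 0.5,
) -> FeatureCurve:
    """Cast each curve sample onto the bone along a fixed direction.

    Every sample is intersected with the mesh along the line through it with
    the given direction (both senses); the intersection nearest to the sample
    is taken.  Samples whose line misses the mesh fall back to the closest
    point on the mesh and are flagged.  If more than ``max_miss_fraction`` of
    the samples miss, the curve is not over the bone and a
    :class:`ProjectionFailedError` is raised (raise the threshold for curves
    that deliberately overhang the condylar silhouette).
    """
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("projection direction must be non-zero")
    d = d / nd
    pts = curve.points
    # cast a single ray per sample from far behind so every line/mesh
    # intersection (both senses from the sample) is collected
    reach = float(femur.scale) + 1.0
    origins = pts - reach * d
    dirs = np.tile(d, (len(pts), 1))
    locations, index_ray, _ = ray_mesh_intersections(femur, origins, dirs)

    projected = np.full_like(pts, np.nan)
    best = np.full(len(pts), np.inf)
    for loc, ray in zip(locations, index_ray):
        dist = np.linalg.norm(loc - pts[ray])
        if dist < best[ray]:
            best[ray] = dist
            projected[ray] = loc
    missed = ~np.isfinite(best)
    if missed.sum() > max_miss_fraction * len(pts):
        raise ProjectionFailedError(
            f"{missed.sum()}/{len(pts)} samples missed the bone mesh; "
            "curve is not over the bone"
        )
    if missed.any():
        closest, _, _ = closest_points_on_mesh(femur, pts[missed])
        projected[missed] = closest
    return FeatureCurve(curve.side, curve.finger_index, projected, curve.knots, flags=missed)


def _vertex_graph(mesh: trimesh.Trimesh) -> nx.Graph:
    # cached on the mesh: segmentation is called repeatedly on the same bone
    # mesh during calibration and the graph only depends on its topology
    cached = mesh.metadata.get("_vertex_graph")
    if cached is not None:
        return cached
    g = nx.Graph()
    lengths = np.linalg.norm(
        mesh.vertices[mesh.edges_unique[:, 0]] - mesh.vertices[mesh.edges_unique[:, 1]], axis=1
    )
    g.add_weighted_edges_from(
        (int(u), int(v), float(w)) for (u, v), w in zip(mesh.edges_unique, lengths)
    )
    mesh.metadata["_vertex_graph"] = g
    return g


def snap_boundary_walk(mesh: trimesh.Trimesh, boundary_points: np.ndarray) -> list[int]:
    """Snap an ordered closed chain of points to a closed vertex walk.

    Each point snaps to its nearest mesh vertex; consecutive snapped vertices
    are joined by shortest edge paths (geodesic bridging of gaps), and the
    walk is closed back to its first vertex.
    """
    tree = mesh.metadata.get("_vertex_kdtree")
    if tree is None:
        tree = cKDTree(mesh.vertices)
        mesh.metadata["_vertex_kdtree"] = tree
    _, vids = tree.query(np.asarray(boundary_points, float))
    chain = [int(vids[0])]
    for v in vids[1:]:
        if int(v) != chain[-1]:
            chain.append(int(v))
    if chain[0] != chain[-1]:
        chain.append(chain[0])
    graph = _vertex_graph(mesh)
    walk = [chain[0]]
    for u, v in zip(chain[:-1], chain[1:]):
        if graph.has_edge(u, v):
            walk.append(v)
        else:
            try:
                path = nx.shortest_path(graph, u, v, weight="weight")
            except nx.NetworkXNoPath as exc:
                raise OpenContourError("boundary cannot be bridged on the mesh") from exc
            walk.extend(path[1:])
    return walk


def segment_by_contours(
    femur: trimesh.Trimesh,
    boundary_points: np.ndarray,
    seed_point=None,
) -> trimesh.Trimesh:
    """Extract the submesh enclosed by a closed chain of projected contours.

    ``boundary_points`` is the ordered concatenation of the projected
    boundary curves (the loop is closed automatically, small gaps bridged by
    shortest paths).  The boundary walk is snapped to mesh edges, face
    adjacency is cut along it, and the connected face component containing
    ``seed_point`` (or the smaller side when the split is unambiguous) is
    returned.
    """
    walk = snap_boundary_walk(femur, boundary_points)
    cut = {frozenset(e) for e in zip(walk[:-1], walk[1:])}

    adjacency = femur.face_adjacency
    shared = femur.face_adjacency_edges
    keep = np.array(
        [frozenset(e) not in cut for e in shared], dtype=bool
    )
    kept = adjacency[keep]
    n = len(femur.faces)
    graph = coo_matrix(
        (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)

    if n_comp == 1:
        # a walk running along the open border of the mesh encloses everything
        edge_faces = trimesh.grouping.group_rows(femur.edges_sorted, require_count=1)
        border = {frozenset(femur.edges_sorted[i]) for i in edge_faces}
        if cut and cut <= border:
            return femur.copy()
        raise OpenContourError("boundary walk did not separate the mesh")

    if seed_point is not None:
        _, _, fid = closest_points_on_mesh(femur, np.atleast_2d(seed_point))
        target = int(labels[int(fid[0])])
    else:
        areas = np.array(
            [femur.area_faces[labels == i].sum() for i in range(n_comp)]
        )
        order = np.argsort(areas)
        if n_comp > 1 and areas[order[0]] > 0.5 * areas[order[-1]]:
            raise SeedRequiredError(
                "both sides of the cut have similar area; pass an interior seed point"
            )
        target = int(order[0])
    faces = np.flatnonzero(labels == target)
    if len(faces) == 0:
        raise EmptySelectionError("contour encloses no faces")
    sub = femur.submesh([faces], append=True)
    return sub


def _boundary_loops(mesh: trimesh.Trimesh) -> list[list[int]]:
    """Vertex loops of all open boundaries (each edge used by one face)."""
    idx = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
    edges = mesh.edges_sorted[idx]
    if len(edges) == 0:
        return []
    g = nx.Graph()
    g.add_edges_from(map(tuple, edges))
    return [list(c) for c in nx.cycle_basis(g)] or [
        list(c) for c in nx.connected_components(g)
    ]


def reconstruct_attachment(
    submesh: trimesh.Trimesh, smoothing_passes: int = 1
) -> trimesh.Trimesh:
    """Reconstruct the attachment surface from a segmented bone patch.

    Interior holes (every boundary loop except the longest, outer one) are
    fan-filled; interior vertices are then Laplacian-faired for
    ``smoothing_passes`` iterations while every boundary vertex stays exactly
    fixed.  The Laplacian update is projected onto the vertex normal
    (relaxation 0.5), which flattens mesh bumps without sliding vertices
    tangentially across the surface.  With no holes and zero passes the input
    is returned unchanged.
    """
    if trimesh.grouping.group_rows(submesh.edges_sorted, require_count=3).size:
        raise ReconstructionError("submesh is non-manifold (edge shared by >2 faces)")
    mesh = submesh.copy()
    loops = _boundary_loops(mesh)
    if len(loops) > 1:
        def loop_length(loop):
            v = mesh.vertices[loop]
            return np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum()

        loops_sorted = sorted(loops, key=loop_length, reverse=True)
        new_faces = []
        for hole in loops_sorted[1:]:
            if len(hole) < 3:
                continue
            v0 = hole[0]
            for a, b in zip(hole[1:-1], hole[2:]):
                new_faces.append([v0, a, b])
        if new_faces:
            mesh = trimesh.Trimesh(
                vertices=mesh.vertices.copy(),
                faces=np.vstack([mesh.faces, np.asarray(new_faces, int)]),
                process=False,
            )
            trimesh.repair.fix_normals(mesh)

    if smoothing_passes > 0:
        fixed = np.zeros(len(mesh.vertices), dtype=bool)
        idx = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
        fixed[np.unique(mesh.edges_sorted[idx].ravel())] = True
        e = mesh.edges_unique
        n = len(mesh.vertices)
        adj = coo_matrix(
            (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        ).tocsr()
        degree = np.asarray(adj.sum(axis=1)).ravel()
        degree[degree == 0] = 1.0
        verts = mesh.vertices.copy()
        interior = ~fixed
        normals = np.asarray(mesh.vertex_normals, float).copy()
        for _ in range(smoothing_passes):
            delta = 0.5 * (adj @ verts / degree[:, None] - verts)
            along = np.einsum("ij,ij->i", delta, normals)[:, None] * normals
            verts[interior] += along[interior]
        mesh = trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(), process=False)
    return mesh
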