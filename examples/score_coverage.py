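"""Score image-overlap consistency: ideal spiral vs a lawn with coverage holes.

Builds the paired fixture scenarios, links cameras whose footprints overlap
by at least 15%, and applies the survey-consistency metric: pool, over all
camera pairs closer than twice the median link length, the shortest-path
length in links between them.  Mass at 1-2 links means a tight
photogrammetric network; mass at 3+ links (or unreachable pairs) marks
coverage holes.
"""

from spiralsurvey import (
    build_link_graph,
    compare_surveys,
    coverage_metric,
    generate_fixtures,
    reference_camera,
)

camera = reference_camera()
fixtures = generate_fixtures(seed=0)

reports = {}
for name in ("spiral_ideal", "lawn_holes"):
    graph = build_link_graph(fixtures[name], camera)
    reports[name] = coverage_metric(graph)
    rep = reports[name]
    print(f"{name}: {rep.n_cameras} cameras, {rep.n_links} links, "
          f"median link {rep.median_link_length:.2f} m")
    print(f"  histogram: { {k: round(v, 4) for k, v in rep.normalized_histogram.items()} }"
          f"  unreachable pairs: {rep.unreachable_pairs}")

summary = compare_surveys(reports["spiral_ideal"], reports["lawn_holes"])
print()
print(f"spiral mass at 1-2 links: {summary['a']['mass_1_2']:.4f}")
print(f"lawn-with-holes mass at 1-2 links: {summary['b']['mass_1_2']:.4f}")
print(f"lawn max path length: {summary['b']['max_path_length']} links")
print()
print("The spiral keeps all nearby camera pairs within two links; the two")
print("injected frame-drop holes in the lawn force detours of 3-4 links,")
print("the signature of a poorly constrained reconstruction region.")
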