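"""Extract morphology and dynamic-region features from a mask movie.

Scripts two cells — one drifting with a transient protrusion, one
static — renders them as labelled cell/nucleus masks, and runs the
18-variable feature extraction. Protrusion/retraction/short-lived
areas come from mask differencing between consecutive frames.
"""

from migvar import Bump, CellScript, MaskMovieSpec, extract_features, generate_mask_movie

spec = MaskMovieSpec(
    n_frames=6,
    image_size=(90, 90),
    pixel_size=0.826,   # um per pixel
    frame_interval=5.0,  # minutes
    cells=(
        CellScript(label=1, center=(28, 28), radius=9, velocity=(1.5, 0.5),
                   bumps=(Bump(frame=2, radius=3.0, angle=0.8, lifetime=1),)),
        CellScript(label=2, center=(62, 62), radius=8),
    ),
)
movie, truth = generate_mask_movie(spec)
feats = extract_features(movie)

print(f"{feats.label.nunique()} cells x {movie.n_frames} frames, "
      f"{feats.shape[0]} rows")
cols = ["label", "frame", "cell_area", "cell_form_factor", "cell_speed",
        "protrusion_area", "retraction_area", "shortlived_area"]
print(feats[cols].round(2).to_string(index=False))
print("\nthe transient bump on cell 1 at frame 2 shows up as matching "
      "protrusion (vs frame 1), retraction (vs frame 3) and short-lived area;")
print("areas are um^2; speed is the cell-centroid displacement in um/min.")
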