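"""Per-patient embedding, clustering, and semi-supervised labeling.

Embeds 80 records of one synthetic patient (deep-feature record vectors ->
PCA -> t-SNE), clusters the 2-D points with a Bayesian Gaussian mixture,
identifies each cluster's centroid record, propagates the centroid's
channel labels to the whole cluster, and builds the distance-ordered review
queue a human labeler would page through (15 thumbnails per page).
"""

import numpy as np

import spectroseize as sz
from spectroseize import embedding, labeling, pipeline

archetype = sz.PatientArchetype("P00", n_seizure_morphologies=2, seizure_rate=0.4,
                                seed=5, burst_rate=0.0)
rng = np.random.default_rng(5)
records_truths = [sz.simulate_record(archetype, 90, "LE", rng, record_id=f"R{i:04d}")
                  for i in range(80)]
records = [r for r, _ in records_truths]
truth_by_id = {r.record_id: t for r, t in records_truths}

# surrogate extractor at reduced feature depth (depth 2048 reproduces the
# standard 131,072-feature channel vectors)
extractor = embedding.SurrogateExtractor(depth=32, seed=0)
points, model = pipeline.embed_patient(records, extractor, rng=np.random.default_rng(0))

print(f"{len(points)} records embedded; mixture allowed up to "
      f"{model.n_components_max} components, used {model.effective_clusters}")

for cluster, centroid in sorted(model.centroid_records.items()):
    members = model.members(cluster)
    queue = labeling.build_review_queue(points, members, centroid)
    centroid_labels = truth_by_id[centroid].channel_labels  # human labels these
    table = labeling.propagate_labels(archetype.patient_id, members, centroid,
                                      centroid_labels)
    n_prop = (table["source"] == "propagated").sum()
    truth_cls = [labeling.record_binary_label(truth_by_id[m].channel_labels.values())
                 for m in members]
    print(f"cluster {cluster}: {len(members)} records, centroid {centroid} "
          f"({labeling.record_binary_label(centroid_labels.values())}), "
          f"{queue.n_pages} review pages, {n_prop} propagated channel labels, "
          f"member classes {dict(zip(*np.unique(truth_cls, return_counts=True)))}")

# With one human-labeled centroid per cluster, every other record gets its
# labels for free; the review queue orders members so corrections concentrate
# on the last pages.
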