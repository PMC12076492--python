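"""Harvest salt bridges and hydrogen bonds from two toy-oligomer states.

Builds two hexamers with disjoint planted contact networks, detects contacts
over short noisy trajectories, applies the protomer-scope filter (terminal
protomers A and F keep their intraprotomer contacts), and pools the
state-distinguishing descriptors.
"""

from metacv import (
    ContactSet, PlantedContact, ToyOligomerSpec, detect_hbonds, detect_salt_bridges,
    filter_protomer_scope, gen_toy_oligomer, gen_transition_trajectory, occupancy,
    state_descriptor_pool,
)

state_a = gen_toy_oligomer(ToyOligomerSpec(twist=60.0, planted_contacts=[
    PlantedContact("salt_bridge", "A", "B", 4.5),
    PlantedContact("hbond", "E", "F", 2.8)]))
state_b = gen_toy_oligomer(ToyOligomerSpec(twist=60.0, planted_contacts=[
    PlantedContact("salt_bridge", "B", "C", 4.5),
    PlantedContact("hbond", "A", "F", 2.8)]))

traj_a = gen_transition_trajectory(state_a, state_a, 200, noise_sigma=0.08, seed=1)
traj_b = gen_transition_trajectory(state_b, state_b, 200, noise_sigma=0.08, seed=2)


def harvest(traj):
    found = ContactSet([])
    for frame in traj.frames[::20]:
        found = found.union(detect_salt_bridges(frame, traj.topology, cutoff=6.0))
        found = found.union(detect_hbonds(frame, traj.topology, d_cut=3.0, ang_cut=30.0))
    return filter_protomer_scope(found, traj.topology.protomer_map, terminal={"A", "F"})


union = harvest(traj_a).union(harvest(traj_b))
occ_a = occupancy(traj_a, union)
occ_b = occupancy(traj_b, union)
print(f"{len(union)} unique contacts across both states")
for c in union:
    print(f"  {c.label:45s} occ(A)={occ_a[c.label]:.2f} occ(B)={occ_b[c.label]:.2f}")

pool = state_descriptor_pool(occ_a, occ_b, min_occ=0.5)
print(f"descriptor pool (occupied >= 50% in at least one state): {len(pool)} contacts")
print("Contacts occupied in only one state are what the discriminant CV will weight.")
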