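# Bundled elephant night-ethogram configuration.
#
# Frame convention: 1920x1080 pixels, origin top-left, y increasing
# downward.  Zone boxes and geometry are illustrative placements for a
# single indoor-enclosure camera; calibrate against a manually scored
# control period before using on real footage.
fps: 25.0
p_cutoff: 0.5
frame_width: 1920
frame_height: 1080

bodyparts: [head, trunk_root, trunk_tip]
anchor_bodyparts: [head, trunk_root]

behaviors:
  - name: Standing
    default: true          # coded whenever in view and nothing else matches
  - name: Lying down
  - name: Foraging
  - name: Hay-net
  - name: Drinking
  - name: Swaying
    min_duration_s: 5.0    # side-to-side motion only counts if sustained >= 5 s

# Lower priority number wins when several rules match one frame.
zone_rules:
  - behavior: Lying down
    priority: 0
    constraints:
      - {bodypart: head, x: [0, 1920], y: [700, 1080]}   # head near floor level
  - behavior: Foraging
    priority: 1
    constraints:
      - {bodypart: trunk_tip, x: [1450, 1800], y: [550, 850]}  # foraging boxes, back wall
  - behavior: Hay-net
    priority: 2
    constraints:
      - {bodypart: trunk_tip, x: [200, 450], y: [50, 250]}     # hay net, top of enclosure
  - behavior: Drinking
    priority: 3
    constraints:
      - {bodypart: trunk_tip, x: [880, 1120], y: [830, 1020]}  # water bowl
  # Swaying deliberately has no zone rule: it happens anywhere in frame and
  # is detected from trunk-root displacement instead.

# Simulator support: representative (x, y) keypoint placement per behavior,
# before jitter.  Each placement sits inside its behavior's zone box and
# outside every other box.
geometry:
  Standing:
    head: [960, 400]
    trunk_root: [960, 520]
    trunk_tip: [960, 700]
  Swaying:                 # stands in place; oscillation added by the simulator
    head: [960, 400]
    trunk_root: [960, 520]
    trunk_tip: [960, 700]
  Lying down:
    head: [820, 860]
    trunk_root: [860, 890]
    trunk_tip: [700, 930]
  Foraging:
    head: [1450, 430]
    trunk_root: [1500, 540]
    trunk_tip: [1620, 700]
  Hay-net:
    head: [400, 340]
    trunk_root: [420, 460]
    trunk_tip: [320, 150]
  Drinking:
    head: [950, 620]
    trunk_root: [945, 680]
    trunk_tip: [1000, 920]
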