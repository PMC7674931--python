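# Behavioral category (cluster) map: category -> glossary codes.
# Categories color the flowchart rectangles; user-overridable.
exploratory:
  - ER      # erect posture
  - IM      # immobility
  - LY      # lying posture
  - NOD     # nodding
  - SC      # scanning
  - SN      # sniffing
  - WA      # walking
grooming:
  - GRB     # grooming (generic)
  - GRF     # grooming of face
  - GRG     # grooming of genitals
  - GRH     # grooming of head
  - GRL     # grooming of body, left
  - GRR     # grooming of body, right
  - LI      # licking
  - LIC     # licking of claws
  - LCL_1   # licking of claws left, forelegs
  - LCL_2   # licking of claws left, hindlegs
  - LCR_1   # licking of claws right, forelegs
  - LCR_2   # licking of claws right, hindlegs
  - SCRL    # scratching of body, left
  - SCRR    # scratching of body, right
limbic:
  - AF      # atonic falling
  - AS      # abdominal spasms
  - EB      # eye blinking
  - EXT     # extension
  - FALL    # falling
  - FALL_MULTIPLE
  - JP      # jumping
  - MT      # masticatory movements
  - MYO_1   # myoclonus spasms, forelegs
  - MYO_g   # generalized myoclonus
  - MYO_h   # myoclonus spasms, head
  - PIM     # postictal immobility
  - REAR    # rearing
  - SAL     # salivation
  - TC      # tonic-clonic seizure
  - TNBL    # tonic neck and body turning left
  - TNBR    # tonic neck and body turning right
fear/aversion:
  - AR      # arousal
  - EXC     # excretion of feces
  - FR      # freezing
  - RU      # running
  - STA     # startle
  - WI      # withdraw
  - YA      # yawning
procursive:
  - GL      # gyrating, left
  - GR      # gyrating, right
  - PIV     # pivoting
other:
  - GN      # gnawing
  - SH      # head shaking
  - WDS     # wet dog shaking
  - UNCODED
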