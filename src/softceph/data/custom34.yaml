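# 34-point soft-tissue landmark schema for multipose orthognathic photographs.
# Indices in this file are 1-based (clinical numbering); the library converts
# to 0-based internally.  Scale0/Scale1 are the endpoints of the 1 cm scale
# bar included in every photograph for mm calibration.
name: custom34
n_points: 34
names:
  - TR     # 1  right tragus
  - GoR    # 2  right soft gonion
  - Gna    # 3  gnathion (lowest mental soft-tissue point, "Mes")
  - GoL    # 4  left soft gonion
  - TL     # 5  left tragus
  - N      # 6  nasion
  - Prn    # 7  pronasale
  - AcR    # 8  right alar curvature
  - Sn     # 9  subnasale
  - AcL    # 10 left alar curvature
  - ExR    # 11 right exocanthion
  - UPmR   # 12 right upper palpebral margin
  - EnR    # 13 right endocanthion
  - LPmR   # 14 right lower palpebral margin
  - EnL    # 15 left endocanthion
  - UPmL   # 16 left upper palpebral margin
  - ExL    # 17 left exocanthion
  - LPmL   # 18 left lower palpebral margin
  - CR     # 19 right cheilion
  - Ls     # 20 labiale superius
  - CL     # 21 left cheilion
  - Li     # 22 labiale inferius
  - Sts    # 23 stomion superius
  - Sti    # 24 stomion inferius
  - PuR    # 25 right pupil
  - PuL    # 26 left pupil
  - UI     # 27 upper incisor
  - LI     # 28 lower incisor
  - Ss     # 29 subspinale ("As")
  - Sl     # 30 sublabiale ("IIs")
  - Pog    # 31 soft pogonion
  - Gn     # 32 soft gnathion
  - Scale0 # 33 scale-bar end "0"
  - Scale1 # 34 scale-bar end "1"
mirror_pairs:   # 1-based, swapped under horizontal flip
  - [1, 5]      # TR <-> TL
  - [2, 4]      # GoR <-> GoL
  - [8, 10]     # AcR <-> AcL
  - [11, 17]    # ExR <-> ExL
  - [12, 16]    # UPmR <-> UPmL
  - [13, 15]    # EnR <-> EnL
  - [14, 18]    # LPmR <-> LPmL
  - [19, 21]    # CR <-> CL
  - [25, 26]    # PuR <-> PuL
  - [33, 34]    # Scale0 <-> Scale1
ion_pair: [11, 17]       # ExR, ExL — interocular normalization
scale_pair: [33, 34]     # Scale0, Scale1
scale_length_mm: 10.0
# Landmarks NOT annotated in a pose (1-based).  UI/LI need an open or smiling
# mouth; LI is additionally hidden in a postural smile; the cheilions are not
# visible on a pure lateral view.
pose_hidden:
  RFV: [27, 28]
  SMO: []
  LMO: []
  PS: [28]
  RLV: [19, 21, 27, 28]
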