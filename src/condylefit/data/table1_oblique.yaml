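# Joint DOF angle constraints (degrees) for the condyle-based (oblique-axis)
# model, for right legs; yaw/roll bounds are sign-inverted for left legs.
front:
  ThCx: {yaw: [-70, 70], pitch: [-33, 147], roll: [-160, 50]}
  CxTr: {yaw: [-20, 160], pitch: [-108, 72], roll: [-120, 120]}
  TrFe: {yaw: [-90, 90], pitch: [-108, 72], roll: [-90, 90]}
  FeTi: {yaw: [-20, 145], pitch: [-75, 75], roll: [-90, 90]}
  TiTar: {yaw: [-60, 120], pitch: [-75, 75]}
middle:
  ThCx: {yaw: [-90, 60], pitch: [-40, 140], roll: [-90, 90]}
  CxTr: {yaw: [-140, 10], pitch: [-54, 126], roll: [-90, 90]}
  TrFe: {yaw: [-110, 110], pitch: [-123, 57], roll: [-110, 90]}
  FeTi: {yaw: [0, 170], pitch: [-90, 90], roll: [-90, 90]}
  TiTar: {yaw: [-10, 140], pitch: [-64, 116]}
hind:
  ThCx: {yaw: [-90, 60], pitch: [-39, 141], roll: [-100, 100]}
  CxTr: {yaw: [-110, 30], pitch: [-121, 59], roll: [-90, 110]}
  TrFe: {yaw: [-90, 90], pitch: [-54, 126], roll: [-90, 90]}
  FeTi: {yaw: [10, 180], pitch: [-103, 77], roll: [-90, 90]}
  TiTar: {yaw: [-5, 90], pitch: [-85, 95]}
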