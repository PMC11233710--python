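# Joint DOF angle constraints (degrees) for the orthogonalized model variant,
# for right legs; yaw/roll bounds are sign-inverted for left legs.
front:
  ThCx: {yaw: [-70, 90], pitch: [-75, 75], roll: [-220, 0]}
  CxTr: {yaw: [-180, 60], pitch: [-75, 75], roll: [-90, 120]}
  TrFe: {yaw: [-90, 90], pitch: [-75, 75], roll: [-90, 90]}
  FeTi: {yaw: [-20, 145], pitch: [-75, 75], roll: [-90, 90]}
  TiTar: {yaw: [-60, 120], pitch: [-75, 75]}
middle:
  ThCx: {yaw: [-75, 75], pitch: [-20, 60], roll: [-75, 75]}
  CxTr: {yaw: [-20, 130], pitch: [-75, 75], roll: [-90, 90]}
  TrFe: {yaw: [-90, 90], pitch: [-75, 75], roll: [-110, 90]}
  FeTi: {yaw: [-170, 10], pitch: [-90, 90], roll: [-90, 90]}
  TiTar: {yaw: [0, 90], pitch: [-60, 60]}
hind:
  ThCx: {yaw: [-90, 90], pitch: [-75, 75], roll: [-45, 130]}
  CxTr: {yaw: [-20, 150], pitch: [-75, 75], roll: [-90, 90]}
  TrFe: {yaw: [-90, 90], pitch: [-75, 75], roll: [-45, 45]}
  FeTi: {yaw: [-150, 20], pitch: [-75, 75], roll: [-90, 90]}
  TiTar: {yaw: [-90, 90], pitch: [-75, 75]}
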