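{
 "hpo_mini_synthetic.obo": "900752ac63c7fae65f2f254bf7ae07a06bd45b4b367406c8588ee6d456c23b42",
 "knowledge_base.yaml": "7a0c30d4e3d3b903205671d36f4c049034032353d70824e0558a8ba59760ac35",
 "table2_reportable.tsv": "6ea012b55578c157ef01086ce99510eb87c39de3d6a7a20f580eef4dca7c7823",
 "table3_unreportable.tsv": "732e0f0ee809b09cf1107aaab9dfdcc1aa8eab5f17d7569fd0c6252a8b23491d"
}
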