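{% extends "base.html" %}
{% block title %}{{ entry.name }}{% endblock %}
{% block heading %}<em>{{ entry.name }}</em>{% endblock %}
{% block content %}
{% if entry.epithet %}
<p>Specific name: <a href="{{ links.specific(entry.epithet) }}"><em>{{ entry.epithet }}</em></a></p>
{% endif %}
<h2>Usage</h2>
<table>
<tr><th>Publication</th><th>Where</th><th>Context</th><th>Accepted species</th></tr>
{% for row in entry.rows %}
<tr>
  <td><a href="{{ links.publication(row.pub_key) }}">{{ row.pub_key }}</a></td>
  <td>{{ row.locus }}</td>
  <td>{{ row.context_summary }}</td>
  <td>{{ row.accepted_display }}</td>
</tr>
{% endfor %}
</table>
{% if entry.species_ids %}
<p>This name has been applied to:
{% for sid in entry.species_ids %}
  <a href="{{ links.species(sid) }}"><em>{{ species_label(sid) }}</em></a>{{ "," if not loop.last }}
{% endfor %}
</p>
{% endif %}
{% endblock %}
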